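"""Synthetic charge-variant benchmark data.

Emulates the experiment that parameterized the solubility surface: a
disordered "wild-type" chain plus two charge-sign-flipped variants — an
acidic one (every K/R replaced by E) and a basic one (every D/E replaced
by K) — whose solubility is measured across a pH grid.  Flipping only
the charged positions keeps the apolar scaffold identical, so the three
variants differ in net charge and isoelectric point while sharing their
non-ionizable composition; this spreads the (L, |Q|) design over the
surface and makes all four coefficients identifiable.

Measurements are drawn from the solubility surface at the true
parameters plus additive homoscedastic Gaussian noise; the default noise
standard deviation is 2% of the noiseless score range, and a seed fixes
every random draw.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .charge import net_charge
from .model import PUBLISHED_PARAMS, SolubilityModelParams, predict_solubility
from .profile import lipophilicity_profile
from .scales import IonizationTable, LipophilicityScale
from .sequence_io import ProteinSequence

__all__ = [
    "SyntheticDesign",
    "make_idp_sequence",
    "flip_charges",
    "make_variant_set",
    "generate_solubility_data",
]

# IDP-like composition: enriched in charged and disorder-promoting
# residues (D/E/K/R/S/P/G/Q), depleted in aromatics, branched apolars
# and cysteine.  Weights for the non-charged portion of the chain.
_NEUTRAL_WEIGHTS = {
    "S": 0.16, "P": 0.14, "G": 0.16, "Q": 0.12, "N": 0.08, "T": 0.09,
    "A": 0.10, "H": 0.03, "M": 0.03, "L": 0.04, "V": 0.02, "I": 0.01,
    "F": 0.01, "Y": 0.005, "W": 0.0, "C": 0.0, "K": 0.0, "R": 0.0,
    "D": 0.0, "E": 0.0,
}
_CHARGED_WEIGHTS = {"D": 0.25, "E": 0.25, "K": 0.25, "R": 0.25}


@dataclass(frozen=True)
class SyntheticDesign:
    """Study conditions for the synthetic benchmark.

    Defaults mirror the original experiment's scale: a 230-residue
    disordered chain with 40% charged residues, three charge variants,
    ten pH points spanning the acid-to-base range, and measurement noise
    of 2% of the noiseless score range.
    """

    length: int = 230
    charged_fraction: float = 0.4
    ph_grid: tuple = tuple(np.linspace(2.0, 12.0, 10).round(6))
    noise_sd: float | None = None  # None -> 2% of the noiseless score range
    true_params: SolubilityModelParams = PUBLISHED_PARAMS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 5:
            raise ValueError("length must allow at least one profile window")
        if not (0.0 <= self.charged_fraction <= 1.0):
            raise ValueError("charged_fraction must lie in [0, 1]")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def make_idp_sequence(design: SyntheticDesign) -> ProteinSequence:
    """Draw a disorder-like random sequence; the design seed fixes it."""
    rng = np.random.default_rng(design.seed)
    n_charged = int(round(design.charged_fraction * design.length))
    n_neutral = design.length - n_charged
    neutral_aas = list(_NEUTRAL_WEIGHTS)
    neutral_p = np.array(list(_NEUTRAL_WEIGHTS.values()))
    neutral_p = neutral_p / neutral_p.sum()
    charged_aas = list(_CHARGED_WEIGHTS)
    charged_p = np.array(list(_CHARGED_WEIGHTS.values()))
    charged_p = charged_p / charged_p.sum()
    residues = list(rng.choice(neutral_aas, size=n_neutral, p=neutral_p)) + list(
        rng.choice(charged_aas, size=n_charged, p=charged_p)
    )
    rng.shuffle(residues)
    return ProteinSequence(id="wildtype", residues="".join(residues))


_ACIDIC_MAP = {"K": "E", "R": "E"}
_BASIC_MAP = {"D": "K", "E": "K"}


def flip_charges(
    seq: ProteinSequence,
    target: str,
    *,
    flip_his: bool = False,
) -> ProteinSequence:
    """Reverse the sign of the charged residues of ``seq``.

    ``target="acidic"`` maps K/R -> E; ``target="basic"`` maps D/E -> K.
    No other position changes and the length is preserved.  Histidine is
    weakly basic and left untouched unless ``flip_his=True`` (acidic
    target only: H -> Q).  A sequence with no charged residues is
    returned unchanged with a warning.
    """
    if target == "acidic":
        mapping = dict(_ACIDIC_MAP)
        if flip_his:
            mapping["H"] = "Q"
        label = "acidic"
    elif target == "basic":
        mapping = dict(_BASIC_MAP)
        label = "basic"
    else:
        raise ValueError(f"target must be 'acidic' or 'basic', got {target!r}")
    if not any(aa in "DEKR" for aa in seq.residues):
        warnings.warn(
            f"{seq.id!r} has no charged residues; flip_charges is a no-op",
            stacklevel=2,
        )
        return seq
    flipped = "".join(mapping.get(aa, aa) for aa in seq.residues)
    return ProteinSequence(
        id=f"{seq.id}_{label}",
        residues=flipped,
        n_term_blocked=seq.n_term_blocked,
        c_term_blocked=seq.c_term_blocked,
    )


def make_variant_set(design: SyntheticDesign) -> list[ProteinSequence]:
    """Wild-type plus its acidic and basic charge-flip variants."""
    wt = make_idp_sequence(design)
    return [wt, flip_charges(wt, "acidic"), flip_charges(wt, "basic")]


def generate_solubility_data(
    variants: list[ProteinSequence],
    design: SyntheticDesign,
    scale: LipophilicityScale,
    table: IonizationTable,
) -> pd.DataFrame:
    """Noisy solubility observations for each variant × pH grid point.

    For each pair the lipophilicity and |net charge| predictors are
    computed from the sequence, the noiseless score is evaluated at the
    design's true parameters, and seeded Gaussian noise is added.
    Returns a frame with columns ``variant, ph, lipophilicity,
    abs_net_charge, solubility`` ready for :class:`~idpsol.fit.SolubilityModel`.
    """
    rows = []
    for seq in variants:
        for ph in design.ph_grid:
            prof = lipophilicity_profile(seq, float(ph), scale, table)
            q = net_charge(seq, float(ph), table)
            s0 = predict_solubility(
                prof.global_lipophilicity, q.abs_net_charge, design.true_params
            )
            rows.append(
                {
                    "variant": seq.id,
                    "ph": float(ph),
                    "lipophilicity": prof.global_lipophilicity,
                    "abs_net_charge": q.abs_net_charge,
                    "solubility": s0,
                }
            )
    frame = pd.DataFrame(rows)
    sd = design.noise_sd
    if sd is None:
        span = frame["solubility"].max() - frame["solubility"].min()
        sd = 0.02 * float(span)
    rng = np.random.default_rng(design.seed)
    frame["solubility"] = frame["solubility"] + rng.normal(0.0, sd, size=len(frame))
    return frame
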