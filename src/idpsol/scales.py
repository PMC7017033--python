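"""pKa tables and pH-dependent amino-acid lipophilicity.

The lipophilicity of an ionizable residue depends on its protonation
state: the charged species partitions far less into an apolar phase than
the neutral one.  This module represents each residue by two species-level
lipophilicity values (``l_neutral``, ``l_charged``, in log-partition
units) and mixes them at a given pH with the Henderson–Hasselbalch
neutral-species fraction:

    l(pH) = f_neutral(pH) * l_neutral + (1 - f_neutral(pH)) * l_charged

For an acid (D, E, C, Y, C-terminus) the neutral species is the
protonated one, ``f_neutral = 1 / (1 + 10**(pH - pKa))``; for a base
(K, R, H, N-terminus) the neutral species is the deprotonated one,
``f_neutral = 1 / (1 + 10**(pKa - pH))``.  Non-ionizable residues are
pH-invariant.

Both the pKa set and the two-species scale are pluggable: built-ins are
shipped as Python data, and any set can be loaded from (or written to)
a small YAML file so an externally published scale can be dropped in
verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

import yaml

from .errors import ScaleLoadError, TableLoadError, UnknownResidueError

__all__ = [
    "AMINO_ACIDS",
    "N_TERM",
    "C_TERM",
    "IonizableGroup",
    "IonizationTable",
    "LipophilicityScale",
    "load_ionization_table",
    "load_lipophilicity_scale",
    "neutral_fraction",
    "residue_lipophilicity",
]

#: The 20 standard one-letter amino-acid codes.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Labels for the terminal ionizable groups.
N_TERM = "N_TERM"
C_TERM = "C_TERM"

#: Side chains that ionize, plus the two termini.
IONIZABLE_GROUPS = frozenset({"D", "E", "C", "Y", "K", "R", "H", N_TERM, C_TERM})


@dataclass(frozen=True)
class IonizableGroup:
    """One ionizable group: a side chain or a chain terminus.

    Parameters
    ----------
    name : str
        One-letter residue code, or ``"N_TERM"`` / ``"C_TERM"``.
    pka : float
        Acid dissociation constant on the log scale; must lie in (0, 14).
    charge_when_ionized : int
        −1 for acids (D, E, C, Y, C-terminus), +1 for bases
        (K, R, H, N-terminus).
    """

    name: str
    pka: float
    charge_when_ionized: int

    def __post_init__(self) -> None:
        if not (0.0 < self.pka < 14.0):
            raise TableLoadError(
                f"pKa for group {self.name!r} must lie in (0, 14), got {self.pka}"
            )
        if self.charge_when_ionized not in (-1, 1):
            raise TableLoadError(
                f"charge_when_ionized for {self.name!r} must be -1 or +1, "
                f"got {self.charge_when_ionized}"
            )

    @property
    def is_acid(self) -> bool:
        return self.charge_when_ionized == -1


class IonizationTable:
    """Immutable collection of :class:`IonizableGroup` covering all
    ionizable side chains and both termini."""

    def __init__(self, name: str, groups: Iterable[IonizableGroup]):
        self._name = str(name)
        self._groups = {g.name: g for g in groups}
        missing = IONIZABLE_GROUPS - set(self._groups)
        if missing:
            raise TableLoadError(
                f"ionization table {name!r} is missing groups: "
                + ", ".join(sorted(missing))
            )
        extra = set(self._groups) - IONIZABLE_GROUPS
        if extra:
            raise TableLoadError(
                f"ionization table {name!r} has unknown groups: "
                + ", ".join(sorted(extra))
            )

    @property
    def name(self) -> str:
        return self._name

    def __getitem__(self, code: str) -> IonizableGroup:
        try:
            return self._groups[code]
        except KeyError:
            raise UnknownResidueError(
                f"{code!r} is not an ionizable group in table {self._name!r}"
            ) from None

    def __contains__(self, code: str) -> bool:
        return code in self._groups

    def __iter__(self):
        return iter(self._groups.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IonizationTable):
            return NotImplemented
        return self._name == other._name and self._groups == other._groups

    def side_chains(self) -> list[IonizableGroup]:
        return [g for g in self if g.name not in (N_TERM, C_TERM)]

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "name": self._name,
            "groups": {
                g.name: {"pka": g.pka, "charge_when_ionized": g.charge_when_ionized}
                for g in self
            },
        }
        Path(path).write_text(yaml.safe_dump(payload), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "IonizationTable":
        try:
            payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise TableLoadError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(payload, dict) or "groups" not in payload:
            raise TableLoadError(f"{path} does not look like an ionization table")
        groups = []
        for name, spec in payload["groups"].items():
            try:
                pka = float(spec["pka"])
                charge = int(spec["charge_when_ionized"])
            except (KeyError, TypeError, ValueError) as exc:
                raise TableLoadError(
                    f"bad entry for group {name!r} in {path}: {exc}"
                ) from exc
            groups.append(IonizableGroup(name, pka, charge))
        return cls(payload.get("name", Path(path).stem), groups)


# Bjellqvist-style pKa set (the values behind the classic ExPASy
# Compute pI/MW tool); the default, and the set under which the
# reference pI values in this package's tests were computed.
_BJELLQVIST = [
    ("D", 4.05, -1),
    ("E", 4.45, -1),
    ("C", 9.00, -1),
    ("Y", 10.00, -1),
    (C_TERM, 3.55, -1),
    ("H", 5.98, +1),
    ("K", 10.00, +1),
    ("R", 12.00, +1),
    (N_TERM, 7.50, +1),
]

# EMBOSS pKa set, as an alternative standard table.
_EMBOSS = [
    ("D", 3.90, -1),
    ("E", 4.10, -1),
    ("C", 8.50, -1),
    ("Y", 10.10, -1),
    (C_TERM, 3.60, -1),
    ("H", 6.50, +1),
    ("K", 10.80, +1),
    ("R", 12.50, +1),
    (N_TERM, 8.60, +1),
]

BUILTIN_TABLES = {
    "bjellqvist": _BJELLQVIST,
    "emboss": _EMBOSS,
}

DEFAULT_TABLE_NAME = "bjellqvist"


def load_ionization_table(
    source: Union[str, Path, None] = None,
) -> IonizationTable:
    """Load a pKa table from a built-in name or a YAML file.

    ``source=None`` returns the default (Bjellqvist-style) table.
    """
    if source is None:
        source = DEFAULT_TABLE_NAME
    if isinstance(source, str) and source in BUILTIN_TABLES:
        groups = [IonizableGroup(n, p, c) for n, p, c in BUILTIN_TABLES[source]]
        return IonizationTable(source, groups)
    path = Path(source)
    if not path.exists():
        raise TableLoadError(
            f"{source!r} is neither a built-in table "
            f"({', '.join(sorted(BUILTIN_TABLES))}) nor a readable file"
        )
    return IonizationTable.from_yaml(path)


class LipophilicityScale:
    """Two-species lipophilicity values for all 20 standard residues.

    ``neutral[aa]`` is the lipophilicity of the neutral species,
    ``charged[aa]`` that of the ionized species (equal to the neutral
    value for non-ionizable residues).  Units are dimensionless
    log-partition units; only differences and weighted averages of these
    values enter downstream scores.  Ionization must never increase
    lipophilicity: ``charged[aa] <= neutral[aa]`` is enforced.
    """

    def __init__(
        self,
        name: str,
        neutral: Mapping[str, float],
        charged: Mapping[str, float] | None = None,
    ):
        self._name = str(name)
        missing = set(AMINO_ACIDS) - set(neutral)
        if missing:
            raise ScaleLoadError(
                f"scale {name!r} is missing residues: " + ", ".join(sorted(missing))
            )
        self._neutral = {aa: float(neutral[aa]) for aa in AMINO_ACIDS}
        if charged is None:
            charged = {}
        self._charged = {
            aa: float(charged.get(aa, self._neutral[aa])) for aa in AMINO_ACIDS
        }
        for aa in AMINO_ACIDS:
            ln, lc = self._neutral[aa], self._charged[aa]
            if not (_finite(ln) and _finite(lc)):
                raise ScaleLoadError(f"non-finite lipophilicity for {aa!r}")
            if lc > ln:
                raise ScaleLoadError(
                    f"charged-species lipophilicity exceeds neutral for {aa!r} "
                    f"({lc} > {ln}); ionization cannot increase lipophilicity"
                )

    @property
    def name(self) -> str:
        return self._name

    def neutral(self, aa: str) -> float:
        self._check(aa)
        return self._neutral[aa]

    def charged(self, aa: str) -> float:
        self._check(aa)
        return self._charged[aa]

    def mean_neutral(self) -> float:
        return sum(self._neutral.values()) / len(self._neutral)

    def _check(self, aa: str) -> None:
        if aa not in self._neutral:
            raise UnknownResidueError(
                f"{aa!r} has no entry in lipophilicity scale {self._name!r}"
            )

    def __eq__(self, other) -> bool:
        if not isinstance(other, LipophilicityScale):
            return NotImplemented
        return (
            self._name == other._name
            and self._neutral == other._neutral
            and self._charged == other._charged
        )

    def to_yaml(self, path: Union[str, Path]) -> None:
        payload = {
            "name": self._name,
            "neutral": self._neutral,
            "charged": self._charged,
        }
        Path(path).write_text(yaml.safe_dump(payload), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "LipophilicityScale":
        try:
            payload = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        except yaml.YAMLError as exc:
            raise ScaleLoadError(f"cannot parse {path}: {exc}") from exc
        if not isinstance(payload, dict) or "neutral" not in payload:
            raise ScaleLoadError(f"{path} does not look like a lipophilicity scale")
        return cls(
            payload.get("name", Path(path).stem),
            payload["neutral"],
            payload.get("charged"),
        )


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


# Neutral-species side-chain lipophilicity: Fauchère–Pliška octanol/water
# π values.  Charged species sit a fixed 0.3 scale units below the
# neutral species.  The gap is expressed in the scale's own units, not in
# raw logD units: the published surface coefficients fix the exchange
# rate between lipophilicity and charge (alpha ≈ -98 per lipophilicity
# unit against gamma ≈ 0.88 per elementary charge), and a species gap
# much larger than ~0.3 would make a single ionization event move the
# lipophilicity term by far more than the corresponding one-unit charge
# shift, contradicting the pH regimes the parameterized model predicts
# (e.g. rising solubility of acidic chains towards neutrality through the
# histidine transition).  This two-species table is a documented default;
# a published pH-dependent scale can replace it via
# LipophilicityScale.from_yaml.
_FP_NEUTRAL = {
    "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
    "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
    "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
    "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
}
_IONIZATION_PENALTY = 0.3
_FP_CHARGED = {
    aa: (_FP_NEUTRAL[aa] - _IONIZATION_PENALTY if aa in IONIZABLE_GROUPS else _FP_NEUTRAL[aa])
    for aa in AMINO_ACIDS
}

BUILTIN_SCALES = {
    "fp-octanol-hh": (_FP_NEUTRAL, _FP_CHARGED),
}

DEFAULT_SCALE_NAME = "fp-octanol-hh"


def load_lipophilicity_scale(
    source: Union[str, Path, None] = None,
) -> LipophilicityScale:
    """Load a lipophilicity scale from a built-in name or a YAML file."""
    if source is None:
        source = DEFAULT_SCALE_NAME
    if isinstance(source, str) and source in BUILTIN_SCALES:
        neutral, charged = BUILTIN_SCALES[source]
        return LipophilicityScale(source, neutral, charged)
    path = Path(source)
    if not path.exists():
        raise ScaleLoadError(
            f"{source!r} is neither a built-in scale "
            f"({', '.join(sorted(BUILTIN_SCALES))}) nor a readable file"
        )
    return LipophilicityScale.from_yaml(path)


def neutral_fraction(pka: float, charge_when_ionized: int, ph: float) -> float:
    """Henderson–Hasselbalch fraction of the neutral species at ``ph``.

    For an acid the neutral species is protonated; for a base it is
    deprotonated.  The returned value lies in (0, 1) and is monotone in pH.
    """
    if charge_when_ionized == -1:
        return 1.0 / (1.0 + 10.0 ** (ph - pka))
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def residue_lipophilicity(
    aa: str,
    ph: float,
    scale: LipophilicityScale,
    table: IonizationTable,
    *,
    allow_unknown: bool = False,
) -> float:
    """Lipophilicity of a single residue at the given pH.

    Non-ionizable residues return their (pH-invariant) scale value.
    Ionizable side chains return the Henderson–Hasselbalch mixture of the
    neutral and charged species values.  Terminal groups are handled at
    the sequence level, not here.

    With ``allow_unknown=True`` the ambiguity code ``X`` maps to the
    scale's mean neutral value; every other unknown code still raises.
    """
    if not (0.0 < ph < 14.0):
        raise ValueError(f"pH must lie in the open interval (0, 14), got {ph}")
    if aa not in AMINO_ACIDS:
        if allow_unknown and aa == "X":
            return scale.mean_neutral()
        raise UnknownResidueError(f"unknown residue code {aa!r}")
    if aa not in table:
        return scale.neutral(aa)
    group = table[aa]
    f = neutral_fraction(group.pka, group.charge_when_ionized, ph)
    return f * scale.neutral(aa) + (1.0 - f) * scale.charged(aa)
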