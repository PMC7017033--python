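"""Sliding-window lipophilicity profiles.

A window of odd size ``w`` slides along the sequence; the mean residue
lipophilicity over the window is assigned to its centre position.  Only
full windows are scored, so a length-``L`` sequence yields exactly
``L - w + 1`` profile points, and the global (whole-chain) lipophilicity
is the unweighted mean of those points.

The window size follows the chain length: 5 for L < 75, 7 for
75 <= L < 175, 9 for 175 <= L < 300 and 11 for L >= 300.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scales import IonizationTable, LipophilicityScale, residue_lipophilicity
from .sequence_io import ProteinSequence

__all__ = ["ProfileResult", "window_size", "lipophilicity_profile"]

MIN_LENGTH = 5


def window_size(length: int) -> int:
    """Odd window size for a chain of ``length`` residues.

    Boundary lengths resolve as half-open intervals: 74 -> 5, 75 -> 7,
    174 -> 7, 175 -> 9, 299 -> 9, 300 -> 11.
    """
    if length < MIN_LENGTH:
        raise ValueError(
            f"sequence of length {length} is too short to profile "
            f"(minimum {MIN_LENGTH})"
        )
    if length < 75:
        return 5
    if length < 175:
        return 7
    if length < 300:
        return 9
    return 11


@dataclass(frozen=True)
class ProfileResult:
    """Per-position window-average lipophilicity at one pH.

    ``positions`` are 1-based window-centre indices; ``values`` the
    corresponding window means.  ``global_lipophilicity`` is the mean of
    ``values`` and is the "Lipophilicity" input of the solubility model.
    """

    sequence_id: str
    ph: float
    window: int
    positions: np.ndarray
    residues: tuple
    values: np.ndarray

    @property
    def global_lipophilicity(self) -> float:
        return float(np.mean(self.values))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.sequence_id,
                "position": self.positions,
                "residue": list(self.residues),
                "window_lipophilicity": self.values,
            }
        )


def lipophilicity_profile(
    seq: ProteinSequence,
    ph: float,
    scale: LipophilicityScale,
    table: IonizationTable,
    *,
    window: int | None = None,
) -> ProfileResult:
    """Sliding-window lipophilicity profile of ``seq`` at ``ph``.

    ``window`` overrides the length-based rule; it must be odd, >= 3 and
    no longer than the sequence.
    """
    w = window_size(len(seq)) if window is None else int(window)
    if w % 2 == 0 or w < 3:
        raise ValueError(f"window size must be odd and >= 3, got {w}")
    if w > len(seq):
        raise ValueError(
            f"window {w} does not fit sequence {seq.id!r} of length {len(seq)}"
        )
    per_residue = np.array(
        [residue_lipophilicity(aa, ph, scale, table) for aa in seq.residues]
    )
    windows = np.lib.stride_tricks.sliding_window_view(per_residue, w)
    means = windows.mean(axis=1)
    half = w // 2
    positions = np.arange(half + 1, len(seq) - half + 1)
    residues = tuple(seq.residues[p - 1] for p in positions)
    return ProfileResult(
        sequence_id=seq.id,
        ph=ph,
        window=w,
        positions=positions,
        residues=residues,
        values=means,
    )
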