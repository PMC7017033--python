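"""Fractional net charge and isoelectric point.

The net charge at a given pH sums Henderson–Hasselbalch fractional
charges over all ionizable groups, side chains and free termini alike:

    Q(pH) = sum_bases 1/(1 + 10**(pH - pKa))
          - sum_acids 1/(1 + 10**(pKa - pH))

Q is continuous and strictly decreasing in pH whenever at least one
ionizable group is present, so the isoelectric point — the root of
Q(pH) = 0 — is unique when it exists.  It exists only for sequences
carrying both acidic and basic groups; all-acidic or all-basic
constructs raise :class:`~idpsol.errors.NoIsoelectricPointError`.

Free cysteines contribute as acids with the table's pKa; disulfide
pairing is not modelled but cysteines can be excluded wholesale with
``include_cys=False``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .errors import NoIsoelectricPointError
from .scales import C_TERM, N_TERM, IonizationTable
from .sequence_io import ProteinSequence

__all__ = ["ChargeResult", "net_charge", "isoelectric_point"]

PH_MIN, PH_MAX = 0.1, 13.9


@dataclass(frozen=True)
class ChargeResult:
    """Net charge of a sequence at one pH, in fractional elementary charges."""

    ph: float
    net_charge: float

    @property
    def abs_net_charge(self) -> float:
        """|Q|, the charge magnitude entering the solubility equation."""
        return abs(self.net_charge)


def _ionizable_counts(
    seq: ProteinSequence, table: IonizationTable, include_cys: bool
) -> list[tuple[float, int, int]]:
    """(pKa, charge_when_ionized, count) for every group present."""
    counts = Counter(seq.residues)
    groups: list[tuple[float, int, int]] = []
    for g in table.side_chains():
        if g.name == "C" and not include_cys:
            continue
        n = counts.get(g.name, 0)
        if n:
            groups.append((g.pka, g.charge_when_ionized, n))
    if not seq.n_term_blocked:
        g = table[N_TERM]
        groups.append((g.pka, g.charge_when_ionized, 1))
    if not seq.c_term_blocked:
        g = table[C_TERM]
        groups.append((g.pka, g.charge_when_ionized, 1))
    return groups


def net_charge(
    seq: ProteinSequence,
    ph: float,
    table: IonizationTable,
    *,
    include_cys: bool = True,
) -> ChargeResult:
    """Fractional net charge of ``seq`` at ``ph``.

    Includes the terminal groups unless the corresponding blocking flag
    is set on the sequence.
    """
    if not (0.0 < ph < 14.0):
        raise ValueError(f"pH must lie in the open interval (0, 14), got {ph}")
    q = 0.0
    for pka, sign, n in _ionizable_counts(seq, table, include_cys):
        if sign > 0:
            q += n / (1.0 + 10.0 ** (ph - pka))
        else:
            q -= n / (1.0 + 10.0 ** (pka - ph))
    return ChargeResult(ph=ph, net_charge=q)


def isoelectric_point(
    seq: ProteinSequence,
    table: IonizationTable,
    *,
    tol: float = 1e-4,
    include_cys: bool = True,
) -> float:
    """pH at which the net charge vanishes, by bisection on [0.1, 13.9].

    Q(pH) is strictly decreasing, so bisection converges to the unique
    root; iteration stops once |Q| <= ``tol``.  Raises
    :class:`NoIsoelectricPointError` if Q keeps one sign over the whole
    interval (no acidic or no basic group).
    """

    def q(ph: float) -> float:
        return net_charge(seq, ph, table, include_cys=include_cys).net_charge

    lo, hi = PH_MIN, PH_MAX
    q_lo, q_hi = q(lo), q(hi)
    if q_lo < 0 or q_hi > 0:
        raise NoIsoelectricPointError(
            f"net charge of {seq.id!r} does not change sign on "
            f"[{PH_MIN}, {PH_MAX}] (Q({PH_MIN})={q_lo:.3g}, "
            f"Q({PH_MAX})={q_hi:.3g}); an isoelectric point requires both "
            "acidic and basic groups"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q_mid = q(mid)
        if abs(q_mid) <= tol and hi - lo <= 1e-6:
            return mid
        if q_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
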