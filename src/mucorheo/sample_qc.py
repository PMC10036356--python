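"""Electrolyte QC, tonicity classification, and pooling arithmetic for ETT mucus.

Endotracheal-tube (ETT) mucus samples are scored by their Na+ and K+
content relative to a physiological reference, classified as hypo-, iso- or
hypertonic, filtered by contamination / volume / tonicity rules, and
combined into isotonic pools either by mixing hypo- and hypertonic
material or by direct NaCl/KCl addition.

Conventions
-----------
* Concentrations in mM, volumes in uL, solids in % w/w, salt masses in mg.
* "Fold concentration" is Na / Na_ref; the with-K variant defaults to
  (Na + K) / (Na_ref + K_ref) but the convention is configurable because
  published usage varies.
* 2(Na + K) is the standard surrogate for total electrolyte concentration
  under monovalent-anion charge balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from mucorheo.errors import InfeasibleMixtureError, InvalidConfigError, InvalidInputError

MW_NACL = 58.44  # g/mol
MW_KCL = 74.55  # g/mol

VALID_FLAGS = frozenset({"blood", "odd_color", "lung_disease"})

Tonicity = Literal["hypotonic", "isotonic", "hypertonic"]


@dataclass(frozen=True)
class SampleRecord:
    """One ETT sample: volume, % solids and cation content.

    ``flags`` carries exclusion-relevant annotations (``blood``,
    ``odd_color``, ``lung_disease``).
    """

    sample_id: str
    volume_ul: float
    pct_solids: float
    na_mM: float
    k_mM: float
    age: float | None = None
    sex: str = "unknown"
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        for name, v in (("na_mM", self.na_mM), ("k_mM", self.k_mM)):
            if not math.isfinite(v) or v < 0:
                raise InvalidInputError(f"{name} must be finite and >= 0, got {v!r}")
        if not math.isfinite(self.volume_ul) or self.volume_ul < 0:
            raise InvalidInputError(f"volume_ul must be >= 0, got {self.volume_ul!r}")
        if not 0.0 <= self.pct_solids <= 100.0:
            raise InvalidInputError(
                f"pct_solids must lie in [0, 100], got {self.pct_solids!r}"
            )
        unknown = set(self.flags) - VALID_FLAGS
        if unknown:
            raise InvalidInputError(f"unknown flags: {sorted(unknown)}")
        object.__setattr__(self, "flags", frozenset(self.flags))


@dataclass(frozen=True)
class TonicityReference:
    """Physiological reference electrolytes and inclusion thresholds.

    The isotonic window is expressed in fold-concentration units
    (Na / na_ref); samples below/above are hypo-/hypertonic.
    """

    na_ref: float = 120.0
    k_ref: float = 15.0
    iso_window: tuple[float, float] = (0.85, 1.25)
    min_volume_ul: float = 100.0
    min_na_plus_k: float = 70.0

    def __post_init__(self):
        lo, hi = self.iso_window
        if not (0.0 < lo < 1.0 < hi):
            raise InvalidConfigError(f"iso_window must straddle 1, got {self.iso_window}")
        if self.na_ref <= 0:
            raise InvalidConfigError("na_ref must be > 0")


@dataclass(frozen=True)
class PoolRecipe:
    """A pooling plan: per-sample aliquots plus optional added salt."""

    entries: tuple  # of (sample_id, aliquot_volume_ul)
    added_nacl_mg: float
    added_kcl_mg: float
    expected_na_mM: float
    expected_k_mM: float

    @property
    def total_volume_ul(self) -> float:
        return sum(v for _, v in self.entries)


@dataclass(frozen=True)
class CohortSummary:
    """Arithmetic means of raw and derived columns over a cohort."""

    n: int
    volume_ul: float
    pct_solids: float
    na_mM: float
    k_mM: float
    na_k_ratio: float
    fold_conc: float
    fold_conc_with_k: float
    surrogate_2nak: float


def electrolyte_surrogate(s: SampleRecord) -> float:
    """Total-electrolyte surrogate 2*(Na + K) in mM."""
    return 2.0 * (s.na_mM + s.k_mM)


def fold_concentration(s: SampleRecord, ref: TonicityReference) -> float:
    """Proportional tonicity difference, Na / Na_ref."""
    if ref.na_ref <= 0:
        raise InvalidConfigError("na_ref must be > 0")
    return s.na_mM / ref.na_ref


def fold_concentration_with_k(
    s: SampleRecord,
    ref: TonicityReference,
    convention: Literal["sum", "na_only"] = "sum",
) -> float:
    """Fold concentration including K.

    The default ``sum`` convention is (Na + K) / (Na_ref + K_ref).
    ``na_only`` falls back to Na / Na_ref for datasets where the with-K
    column was tabulated that way.
    """
    if convention == "na_only":
        return fold_concentration(s, ref)
    denom = ref.na_ref + ref.k_ref
    if denom <= 0:
        raise InvalidConfigError("na_ref + k_ref must be > 0")
    return (s.na_mM + s.k_mM) / denom


def classify_tonicity(s: SampleRecord, ref: TonicityReference) -> Tonicity:
    """hypotonic / isotonic / hypertonic by the fold-concentration window."""
    fold = fold_concentration(s, ref)
    lo, hi = ref.iso_window
    if fold < lo:
        return "hypotonic"
    if fold > hi:
        return "hypertonic"
    return "isotonic"


#: Exclusion reasons, checked in fixed priority order.
_EXCLUSION_CHECKS = ("blood", "odd_color", "lung_disease")


def apply_inclusion_filters(
    cohort: Sequence[SampleRecord], ref: TonicityReference
) -> tuple[list[SampleRecord], list[tuple[SampleRecord, str]]]:
    """Split a cohort into (included, excluded-with-reason).

    Each excluded record carries exactly the first matching reason in the
    fixed priority order: contamination flags (blood, odd_color,
    lung_disease) > low volume > low tonicity.
    """
    if not cohort:
        raise InvalidInputError("cohort must be non-empty")
    included: list[SampleRecord] = []
    excluded: list[tuple[SampleRecord, str]] = []
    for s in cohort:
        reason = None
        for flag in _EXCLUSION_CHECKS:
            if flag in s.flags:
                reason = flag
                break
        if reason is None and s.volume_ul < ref.min_volume_ul:
            reason = "low_volume"
        if reason is None and (s.na_mM + s.k_mM) < ref.min_na_plus_k:
            reason = "low_tonicity"
        if reason is None:
            included.append(s)
        else:
            excluded.append((s, reason))
    return included, excluded


def pooled_concentration(entries: Iterable[tuple[float, float]]) -> float:
    """Volume-weighted mean concentration of mixed aliquots.

    ``entries`` are (concentration_mM, volume_ul) pairs; equal aliquots
    reduce to the arithmetic mean of the concentrations.
    """
    entries = list(entries)
    total_v = sum(v for _, v in entries)
    if total_v <= 0:
        raise InvalidInputError("total aliquot volume must be > 0")
    return sum(c * v for c, v in entries) / total_v


def optimize_mixture(
    candidates: Sequence[SampleRecord],
    ref: TonicityReference,
    min_aliquot_ul: float = 50.0,
    max_aliquot_ul: float = 250.0,
    grid_points: int = 201,
) -> PoolRecipe:
    """Aliquot volumes minimizing |pooled fold concentration - 1|.

    Samples are split into a low side (Na < Na_ref) and a high side; every
    sample on a side receives the same aliquot volume, so the search is
    over the one-dimensional family of high/low volume ratios.  A
    deterministic log-spaced ratio grid is scanned and refined; exact ties
    are broken toward equal aliquots.  The pool is scaled to the largest
    feasible aliquots at the optimal ratio.

    Raises :class:`InfeasibleMixtureError` when no candidate passes the
    inclusion filters or the aliquot bounds cannot be met.
    """
    if min_aliquot_ul <= 0 or max_aliquot_ul < min_aliquot_ul:
        raise InfeasibleMixtureError(
            f"bad aliquot bounds [{min_aliquot_ul}, {max_aliquot_ul}]"
        )
    usable, _ = apply_inclusion_filters(candidates, ref)
    usable = [s for s in usable if min(max_aliquot_ul, s.volume_ul) >= min_aliquot_ul]
    if not usable:
        raise InfeasibleMixtureError("no candidate satisfies filters and aliquot bounds")

    low = [s for s in usable if s.na_mM < ref.na_ref]
    high = [s for s in usable if s.na_mM >= ref.na_ref]

    def _cap(side: list[SampleRecord]) -> float:
        return min(min(max_aliquot_ul, s.volume_ul) for s in side) if side else 0.0

    cap_lo, cap_hi = _cap(low), _cap(high)

    def _recipe(v_lo: float, v_hi: float) -> PoolRecipe:
        entries = tuple(
            (s.sample_id, v_lo if s in low else v_hi) for s in usable
        )
        na = pooled_concentration(
            [(s.na_mM, v) for (sid, v), s in zip(entries, usable)]
        )
        k = pooled_concentration(
            [(s.k_mM, v) for (sid, v), s in zip(entries, usable)]
        )
        return PoolRecipe(entries, 0.0, 0.0, na, k)

    if not low or not high:
        # one-sided pool: equal aliquots are optimal and maximal
        cap = cap_lo or cap_hi
        return _recipe(cap, cap)

    # ratio r = v_hi / v_lo constrained so both sides fit their bounds
    r_min = min_aliquot_ul / cap_lo
    r_max = cap_hi / min_aliquot_ul
    if r_min > r_max:
        raise InfeasibleMixtureError("aliquot bounds admit no high/low ratio")

    def _fold_at(r: float) -> float:
        na = pooled_concentration(
            [(s.na_mM, 1.0) for s in low] + [(s.na_mM, r) for s in high]
        )
        return na / ref.na_ref

    import numpy as np

    grid = np.geomspace(r_min, r_max, grid_points)
    objective = np.abs([_fold_at(r) - 1.0 for r in grid])
    # tie-break toward equal aliquots (r nearest 1)
    best = min(range(len(grid)), key=lambda i: (round(objective[i], 12), abs(math.log(grid[i]))))
    lo_i, hi_i = max(best - 1, 0), min(best + 1, len(grid) - 1)
    # golden-free refinement: fold is monotone in r, bisect on sign of (fold-1)
    a, b = grid[lo_i], grid[hi_i]
    if (_fold_at(a) - 1.0) * (_fold_at(b) - 1.0) < 0:
        for _ in range(80):
            m = math.sqrt(a * b)
            if (_fold_at(a) - 1.0) * (_fold_at(m) - 1.0) <= 0:
                b = m
            else:
                a = m
        r_opt = math.sqrt(a * b)
    else:
        r_opt = grid[best]
    r_opt = min(max(r_opt, r_min), r_max)

    # scale to the largest feasible aliquots at this ratio
    v_lo = min(cap_lo, cap_hi / r_opt)
    v_hi = r_opt * v_lo
    if v_lo < min_aliquot_ul or v_hi < min_aliquot_ul:
        raise InfeasibleMixtureError("optimal ratio violates minimum aliquot volume")
    return _recipe(v_lo, v_hi)


def salt_addition_plan(
    pool_volume_ul: float,
    current: tuple[float, float],
    target: tuple[float, float],
) -> tuple[float, float]:
    """(NaCl mg, KCl mg) to raise a pool from ``current`` to ``target`` (mM).

    mass = delta_c [mol/L] x volume [L] x MW [g/mol].  The solid-volume
    change from the added salt is neglected (<0.5% at these masses).
    Salt can only be added: a target below current raises an error
    pointing the caller at mixing/dilution instead.
    """
    if pool_volume_ul <= 0:
        raise InvalidInputError("pool_volume_ul must be > 0")
    d_na = target[0] - current[0]
    d_k = target[1] - current[1]
    if d_na < 0 or d_k < 0:
        raise InvalidInputError(
            "target below current concentration: salt addition cannot lower "
            "tonicity — dilute or mix with hypotonic material instead"
        )
    # mM * uL * g/mol * 1e-6 -> mg
    nacl_mg = d_na * pool_volume_ul * MW_NACL * 1e-6
    kcl_mg = d_k * pool_volume_ul * MW_KCL * 1e-6
    return nacl_mg, kcl_mg


def dilution_plan(v0_ul: float, c0_pct: float, c_target_pct: float) -> float:
    """Diluent volume (uL) bringing ``c0_pct`` solids down to ``c_target_pct``.

    Mass conservation: (v0 + v_add) * c_target = v0 * c0.
    """
    if v0_ul <= 0:
        raise InvalidInputError("v0_ul must be > 0")
    if not 0 < c_target_pct <= c0_pct:
        raise InvalidInputError(
            f"cannot reach {c_target_pct}% from {c0_pct}% by dilution"
        )
    return v0_ul * (c0_pct / c_target_pct - 1.0)


def cohort_summary(
    cohort: Sequence[SampleRecord],
    ref: TonicityReference,
    with_k_convention: Literal["sum", "na_only"] = "sum",
) -> CohortSummary:
    """Arithmetic means of each raw and derived column."""
    if not cohort:
        raise InvalidInputError("cohort must be non-empty")
    n = len(cohort)

    def _mean(vals):
        return sum(vals) / n

    return CohortSummary(
        n=n,
        volume_ul=_mean([s.volume_ul for s in cohort]),
        pct_solids=_mean([s.pct_solids for s in cohort]),
        na_mM=_mean([s.na_mM for s in cohort]),
        k_mM=_mean([s.k_mM for s in cohort]),
        na_k_ratio=_mean(
            [s.na_mM / s.k_mM if s.k_mM > 0 else math.inf for s in cohort]
        ),
        fold_conc=_mean([fold_concentration(s, ref) for s in cohort]),
        fold_conc_with_k=_mean(
            [fold_concentration_with_k(s, ref, with_k_convention) for s in cohort]
        ),
        surrogate_2nak=_mean([electrolyte_surrogate(s) for s in cohort]),
    )
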