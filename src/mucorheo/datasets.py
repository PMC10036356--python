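"""Bundled ETT mucus characterization tables.

Three small cohorts of endotracheal-tube mucus samples, transcribed from
the published characterization of a one-week (ISO, MIX) and multi-year
(ADD) collection: per-sample volume, % solids and ICP-OES Na+/K+
concentrations.  These drive the tonicity-QC examples and serve as the
reference inputs for pooling arithmetic.

* ISO  — 5 isotonic samples (fold concentration within the physiological
  window).
* MIX  — 3 non-isotonic samples (2 hypotonic + 1 hypertonic) whose
  equal-aliquot pool is isotonic.
* ADD  — 9 uniformly hypotonic (~50% normal tonicity) samples corrected
  by direct NaCl/KCl addition after pooling.
"""

from __future__ import annotations

from mucorheo.sample_qc import SampleRecord

# (age, sex, volume_ul, pct_solids, na_mM, k_mM)
_ISO_ROWS = (
    (29, "M", 75, 4.76, 119.09, 20.47),
    (51, "F", 300, 5.38, 121.77, 15.24),
    (18, "M", 275, 3.25, 110.44, 7.89),
    (75, "F", 700, 7.44, 102.64, 16.23),
    (49, "M", 800, 3.98, 108.71, 13.57),
)

_MIX_ROWS = (
    (62, "M", 2000, 7.14, 99.67, 13.14),
    (61, "F", 330, 4.49, 97.14, 9.27),
    (64, "M", 250, 5.15, 155.49, 15.88),
)

_ADD_ROWS = (
    (64, "F", 500, 4.51, 78.64, 6.03),
    (73, "F", 300, 3.57, 62.14, 16.58),
    (40, "F", 325, 3.77, 65.55, 4.47),
    (66, "M", 300, 5.22, 76.67, 23.62),
    (41, "F", 500, 4.46, 89.04, 14.99),
    (76, "M", 400, 9.69, 51.85, 16.20),
    (67, "F", 300, 5.47, 68.93, 9.59),
    (59, "F", 300, 2.03, 60.90, 7.07),
    (72, "M", 250, 4.55, 40.62, 11.43),
)


def _records(prefix: str, rows) -> list[SampleRecord]:
    return [
        SampleRecord(
            sample_id=f"{prefix}-{i + 1}",
            age=age,
            sex=sex,
            volume_ul=vol,
            pct_solids=solids,
            na_mM=na,
            k_mM=k,
        )
        for i, (age, sex, vol, solids, na, k) in enumerate(rows)
    ]


def iso_cohort() -> list[SampleRecord]:
    """The 5 isotonic (ISO) samples."""
    return _records("ISO", _ISO_ROWS)


def mix_cohort() -> list[SampleRecord]:
    """The 3 non-isotonic (MIX) samples pooled by mixing."""
    return _records("MIX", _MIX_ROWS)


def add_cohort() -> list[SampleRecord]:
    """The 9 hypotonic (ADD) samples corrected by salt addition."""
    return _records("ADD", _ADD_ROWS)
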