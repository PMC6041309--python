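"""Total bacterial load from 16S qPCR, and group comparisons.

A universal 16S rRNA gene assay measures total bacterial DNA per sampling
swab.  Because the mass of material on a swab cannot be quantified, loads
are interpreted as relative copy numbers versus the negative controls and
the other sample groups, summarized by group medians and compared with
the two-tailed Mann–Whitney U test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .similarity import TestResult

logger = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    """Linear qPCR standard curve: Ct = slope · log10(copies) + intercept.

    slope is Ct per decade of template (−3.32 at perfect doubling
    efficiency); ``dynamic_range`` bounds the copy numbers over which the
    curve was calibrated.
    """

    slope: float
    intercept: float
    dynamic_range: tuple[float, float] = (1e2, 1e9)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        lo, hi = self.dynamic_range
        if not (0 < lo < hi):
            raise ValueError("dynamic range bounds must be positive and ordered")


#: Perfect-efficiency default curve for synthetic data: one Ct per template
#: doubling, i.e. slope = -log2(10) = -3.3219 Ct per decade.
DEFAULT_CURVE = StandardCurve(slope=-float(np.log2(10)), intercept=40.0)


@dataclass
class CopyEstimate:
    copies: float
    in_range: bool


def copies_from_ct(ct: float, curve: StandardCurve, dilution: float = 1.0) -> CopyEstimate:
    """Copies per swab from a Ct value: dilution · 10^((ct − intercept)/slope).

    Values outside the curve's dynamic range are flagged but still
    returned (samples exceeding the range must be diluted further before
    amplification).
    """
    if not np.isfinite(ct):
        raise ValueError("Ct must be finite")
    if dilution < 1:
        raise ValueError("dilution factor must be >= 1")
    copies = dilution * 10.0 ** ((ct - curve.intercept) / curve.slope)
    raw = copies / dilution  # range check applies to the amplified template
    in_range = curve.dynamic_range[0] <= raw <= curve.dynamic_range[1]
    if not in_range:
        logger.warning("qPCR estimate %.3g outside dynamic range %s", raw, curve.dynamic_range)
    return CopyEstimate(float(copies), in_range)


@dataclass
class QPCRTable:
    """Per-swab 16S copy numbers with group labels.

    ``frame`` columns: sample_id, group, copies_per_swab (positive), and
    optionally ct and dilution_factor.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        if not {"sample_id", "group"}.issubset(df.columns):
            raise ValueError("qPCR table needs sample_id and group columns")
        if "copies_per_swab" not in df.columns:
            raise ValueError(
                "no copies_per_swab column; derive it from Ct with a StandardCurve "
                "(QPCRTable.from_ct)"
            )
        if (df["copies_per_swab"] <= 0).any():
            raise ValueError("copies_per_swab must be positive")
        if "dilution_factor" in df.columns and (df["dilution_factor"].dropna() < 1).any():
            raise ValueError("dilution_factor must be >= 1")
        self.frame = df.reset_index(drop=True)

    @classmethod
    def from_ct(cls, frame: pd.DataFrame, curve: StandardCurve) -> "QPCRTable":
        """Build a table from Ct values using a standard curve."""
        df = frame.copy()
        dil = df["dilution_factor"] if "dilution_factor" in df.columns else pd.Series(1.0, index=df.index)
        estimates = [copies_from_ct(ct, curve, d) for ct, d in zip(df["ct"], dil.fillna(1.0))]
        df["copies_per_swab"] = [e.copies for e in estimates]
        df["in_dynamic_range"] = [e.in_range for e in estimates]
        return cls(df)

    def group_copies(self, group: str) -> np.ndarray:
        vals = self.frame.loc[self.frame["group"] == group, "copies_per_swab"].to_numpy(float)
        if vals.size == 0:
            raise ValueError(f"no samples in group {group!r}")
        return vals


def read_qpcr_table(path, curve: StandardCurve | None = None) -> QPCRTable:
    df = pd.read_csv(path, sep="\t")
    if "copies_per_swab" not in df.columns and "ct" in df.columns:
        if curve is None:
            raise ValueError("Ct-only table requires a StandardCurve")
        return QPCRTable.from_ct(df, curve)
    return QPCRTable(df)


def group_copy_ratio(table: QPCRTable, group_a: str, group_b: str) -> float:
    """Ratio of median copies per swab between two groups.

    The median of an even-sized group is the midpoint of the two central
    values, so group_copy_ratio(a, b) · group_copy_ratio(b, a) = 1.
    """
    return float(np.median(table.group_copies(group_a)) / np.median(table.group_copies(group_b)))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann–Whitney U test.

    Uses exact null enumeration when the combined sample size is ≤ 16 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections.  Constant pooled data yields p = 1 with a
    warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        logger.warning("constant pooled data: Mann–Whitney test degenerate, p = 1")
        return TestResult(float(a.size * b.size / 2), 1.0, "mann-whitney (degenerate)")
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size + b.size <= 16 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    p = float(min(res.pvalue, 1.0))
    return TestResult(float(res.statistic), p, f"mann-whitney ({method})")
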