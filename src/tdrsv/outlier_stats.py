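"""Expression outliers and enrichment statistics.

Log-scale expression is residualized against supplied covariates
(ordinary least squares, per gene), standardized per gene into Z-scores,
and thresholded into single-tissue (|Z| > 2) or multi-tissue
(|median Z across tissues| > 2) outliers.  Carrier-outlier enrichment is
summarized as an odds ratio with a Woolf 95% CI (Haldane +0.5 correction
when a cell is empty) and a two-sided Fisher exact p-value.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

Z_OUTLIER_THRESHOLD = 2.0  # strict: |Z| must exceed 2


@dataclass
class ExpressionMatrix:
    """Per-tissue sample × gene log-expression plus shared covariates."""

    values: dict[str, pd.DataFrame]
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        for tissue, df in self.values.items():
            if not np.isfinite(df.values).all():
                raise ValueError(f"non-finite expression values in {tissue}")
            if self.covariates is not None and not df.index.equals(
                self.covariates.index
            ):
                raise ValueError(f"covariates not row-aligned to samples in {tissue}")


@dataclass
class ZScoreTable:
    z: dict[str, pd.DataFrame]  # tissue -> sample × gene
    zero_variance: dict[str, list[str]] = field(default_factory=dict)

    @property
    def median_z(self) -> pd.DataFrame:
        """Cross-tissue median Z per sample × gene."""
        stacked = pd.concat(self.z.values(), keys=self.z.keys())
        return stacked.groupby(level=1).median()


def residualize_and_zscore(mat: ExpressionMatrix) -> ZScoreTable:
    """OLS-residualize each gene against the covariates, then standardize.

    Zero-variance genes (including perfect covariate fits) come back as
    NaN columns and are listed in ``zero_variance``.
    """
    z_out: dict[str, pd.DataFrame] = {}
    flagged: dict[str, list[str]] = {}
    for tissue, df in mat.values.items():
        y = df.values.astype(float)
        n = y.shape[0]
        if mat.covariates is not None and mat.covariates.shape[1] > 0:
            x = np.column_stack(
                [np.ones(n), mat.covariates.values.astype(float)]
            )
            beta, *_ = np.linalg.lstsq(x, y, rcond=None)
            resid = y - x @ beta
        else:
            resid = y - y.mean(axis=0, keepdims=True)
        sd = resid.std(axis=0, ddof=1)
        bad = ~(sd > 1e-12)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (resid - resid.mean(axis=0, keepdims=True)) / sd
        z[:, bad] = np.nan
        z_out[tissue] = pd.DataFrame(z, index=df.index, columns=df.columns)
        flagged[tissue] = list(df.columns[bad])
    return ZScoreTable(z=z_out, zero_variance=flagged)


def call_outliers(ztab: ZScoreTable, mode: str = "single") -> dict[str, pd.DataFrame] | pd.DataFrame:
    """Boolean outlier table(s): single |z| > 2, multi |median z| > 2."""
    if mode == "single":
        return {
            tissue: z.abs() > Z_OUTLIER_THRESHOLD for tissue, z in ztab.z.items()
        }
    if mode == "multi":
        return ztab.median_z.abs() > Z_OUTLIER_THRESHOLD
    raise ValueError(f"mode must be 'single' or 'multi', got {mode!r}")


@dataclass
class EnrichmentResult:
    odds_ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float]
    table: tuple[int, int, int, int]  # a, b, c, d
    flags: set[str] = field(default_factory=set)

    @property
    def defined(self) -> bool:
        return self.odds_ratio is not None


def enrichment_from_counts(a: int, b: int, c: int, d: int) -> EnrichmentResult:
    """OR, Woolf 95% CI and Fisher exact p from a 2×2 (a,b,c,d) table.

    Layout: rows = carrier/non-carrier, cols = outlier/non-outlier, so
    a = carrier∧outlier, b = carrier∧¬outlier, c = ¬carrier∧outlier,
    d = neither.  A degenerate table (empty row or column) is UNDEFINED.
    """
    flags: set[str] = set()
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        return EnrichmentResult(None, None, None, None, (a, b, c, d), {"degenerate"})
    if 0 in (a, b, c, d):
        flags.add("haldane_corrected")
        aa, bb, cc, dd = (x + 0.5 for x in (a, b, c, d))
    else:
        aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    or_ = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci_low = float(np.exp(np.log(or_) - 1.96 * se))
    ci_high = float(np.exp(np.log(or_) + 1.96 * se))
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return EnrichmentResult(float(or_), ci_low, ci_high, float(p), (a, b, c, d), flags)


def carrier_outlier_enrichment(
    carriers: pd.DataFrame, outliers: pd.DataFrame
) -> EnrichmentResult:
    """Odds ratio for an SV carrier to be an expression outlier.

    Both inputs are aligned sample × gene boolean tables; cells with a
    NaN outlier status (zero-variance genes) are ignored.
    """
    if not carriers.index.equals(outliers.index) or not carriers.columns.equals(
        outliers.columns
    ):
        raise ValueError("carrier and outlier matrices must be aligned")
    car = carriers.values.astype(bool).ravel()
    out_raw = outliers.values.ravel()
    valid = ~pd.isna(out_raw)
    car, out = car[valid], out_raw[valid].astype(bool)
    a = int(np.sum(car & out))
    b = int(np.sum(car & ~out))
    c = int(np.sum(~car & out))
    d = int(np.sum(~car & ~out))
    return enrichment_from_counts(a, b, c, d)


def tdr_expression_correlation(
    pairs: Iterable[tuple[Optional[float], float]], method: str = "spearman"
) -> tuple[Optional[float], Optional[float]]:
    """Correlation between TDR and tissue-specific expression Z-score.

    Pairs with UNDEFINED TDR (None/NaN) are dropped with a logged count;
    a constant vector yields (None, None).
    """
    arr = [
        (t, z)
        for t, z in pairs
        if t is not None and not np.isnan(t) and not np.isnan(z)
    ]
    if len(arr) < 3:
        raise ValueError(f"need >= 3 defined pairs, got {len(arr)}")
    tdrs = np.array([t for t, _ in arr])
    zs = np.array([z for _, z in arr])
    if np.ptp(tdrs) == 0 or np.ptp(zs) == 0:
        return None, None
    if method == "spearman":
        r, p = stats.spearmanr(tdrs, zs)
    elif method == "pearson":
        r, p = stats.pearsonr(tdrs, zs)
    else:
        raise ValueError(f"method must be 'spearman' or 'pearson', got {method!r}")
    return float(r), float(p)


#: default TSS distance bin edges (bp); upper edge is open-ended
DEFAULT_TSS_BINS = (0, 2_000, 10_000, 100_000, 1_000_000)


def tss_bin_enrichment(
    noncoding_dels: Sequence[tuple[float, bool]],
    background_outliers: Sequence[bool],
    bin_edges: Sequence[float] = DEFAULT_TSS_BINS,
) -> pd.DataFrame:
    """Outlier enrichment of non-coding (TDR = 0) deletions by TSS distance.

    Each carrier row is (distance to nearest TSS, outlier flag); the
    background is outlier flags of non-carrier sample-gene pairs.  A
    single all-covering bin reduces to plain carrier-outlier enrichment.
    """
    bg = np.asarray(background_outliers, dtype=bool)
    c = int(bg.sum())
    d = int((~bg).sum())
    edges = list(bin_edges) + [np.inf]
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = [flag for dist, flag in noncoding_dels if lo <= dist < hi]
        if not in_bin:
            rows.append(
                {
                    "bin_lo": lo,
                    "bin_hi": hi,
                    "n_carriers": 0,
                    "odds_ratio": np.nan,
                    "ci_low": np.nan,
                    "ci_high": np.nan,
                    "p_value": np.nan,
                }
            )
            continue
        a = int(sum(in_bin))
        b = len(in_bin) - a
        res = enrichment_from_counts(a, b, c, d)
        rows.append(
            {
                "bin_lo": lo,
                "bin_hi": hi,
                "n_carriers": len(in_bin),
                "odds_ratio": res.odds_ratio if res.defined else np.nan,
                "ci_low": res.ci_low if res.defined else np.nan,
                "ci_high": res.ci_high if res.defined else np.nan,
                "p_value": res.p_value if res.defined else np.nan,
            }
        )
    return pd.DataFrame(rows)
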