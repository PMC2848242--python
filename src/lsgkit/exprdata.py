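"""Expression tables: IO, detection filters, and diet-within-time contrasts.

Two kinds of input are supported, mirroring two microarray designs:

* a tissue panel of raw intensities (one sample per tissue), filtered by a
  250-unit minimum intensity rule, and
* a peripartal liver time series of log2 expression ratios versus a
  reference pool (time points in days relative to parturition, two diets,
  replicate animals), filtered by a 150-unit minimum raw intensity plus a
  per-spot significance requirement (raw p < 0.05).

In both cases a gene survives if at least one sample-point simultaneously
is flagged present, lies strictly above that sample's negative-control
median, and meets the intensity floor (inclusive).  For the time series
the intensity condition and the significance condition are each evaluated
"in at least one sample-point" independently — they need not hold at the
same sample-point.

The diet effect is estimated per gene by ordinary least squares on
(time, diet) cell means — the fixed effect of diet nested within time
point — with a pooled residual variance, and Benjamini-Hochberg FDR
control applied jointly across all gene x time contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class FilterConfig:
    min_intensity: float  # 250 for the tissue panel, 150 for the liver series
    require_present: bool = True
    require_above_control_median: bool = True
    sig_p: float | None = None  # 0.05 for the liver series, None for the panel

    def __post_init__(self) -> None:
        if self.min_intensity is None or self.min_intensity <= 0:
            raise ValueError("min_intensity must be a positive threshold")
        if self.sig_p is not None and not 0 < self.sig_p <= 1:
            raise ValueError("sig_p must lie in (0, 1]")


@dataclass
class ExpressionMatrix:
    """Genes x samples with intensities, present flags and optional p-values.

    ``meta`` is indexed by sample id and may carry `tissue`, `time`, `diet`,
    `replicate` and `neg_control_median` columns.  ``pvals`` holds the
    per-spot significance of each measurement versus the reference pool
    (time-series data only).
    """

    intensity: pd.DataFrame
    meta: pd.DataFrame
    present: pd.DataFrame | None = None
    pvals: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        dup = self.intensity.index[self.intensity.index.duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene ids: {sorted(dup)}")
        missing = [s for s in self.intensity.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        if self.present is None:
            self.present = pd.DataFrame(
                True, index=self.intensity.index, columns=self.intensity.columns
            )
        self.present = self.present.reindex_like(self.intensity).fillna(False).astype(bool)
        if self.pvals is not None:
            self.pvals = self.pvals.reindex_like(self.intensity)

    @property
    def genes(self) -> list[str]:
        return list(self.intensity.index)

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def subset(self, genes) -> "ExpressionMatrix":
        genes = [g for g in self.intensity.index if g in set(genes)]
        return ExpressionMatrix(
            intensity=self.intensity.loc[genes],
            meta=self.meta,
            present=self.present.loc[genes],
            pvals=None if self.pvals is None else self.pvals.loc[genes],
        )


def read_expression(
    tsv_path,
    metadata_path,
    present_path=None,
    pvals_path=None,
) -> ExpressionMatrix:
    """Read a tab-delimited expression table plus companion metadata.

    Dialect: UTF-8, tab-delimited, '.' decimal; first column gene id,
    header row sample ids.  Present flags (0/1) and per-spot p-values are
    parallel TSVs of identical shape.  Metadata rows are samples with at
    least the columns relevant to the design (tissue, or time/diet/
    replicate) and optionally `neg_control_median`.
    """
    intensity = pd.read_csv(tsv_path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    intensity.columns = intensity.columns.astype(str)
    present = None
    if present_path is not None:
        present = pd.read_csv(present_path, sep="\t", index_col=0).astype(bool)
        present.columns = present.columns.astype(str)
    pvals = None
    if pvals_path is not None:
        pvals = pd.read_csv(pvals_path, sep="\t", index_col=0)
        pvals.columns = pvals.columns.astype(str)
    return ExpressionMatrix(intensity=intensity, meta=meta, present=present, pvals=pvals)


def _detection_mask(m: ExpressionMatrix, cfg: FilterConfig) -> pd.DataFrame:
    """Per-cell: present, above control median (strict), and >= floor."""
    ok = m.intensity >= cfg.min_intensity
    if cfg.require_present:
        ok &= m.present
    if cfg.require_above_control_median:
        if "neg_control_median" not in m.meta.columns:
            raise ValueError("metadata lacks neg_control_median column")
        ctrl = m.meta.loc[m.intensity.columns, "neg_control_median"]
        # equality to the control median fails the "above" test
        ok &= m.intensity.gt(ctrl, axis=1)
    return ok & m.intensity.notna()


def filter_panel(m: ExpressionMatrix, cfg: FilterConfig) -> ExpressionMatrix:
    """Keep genes detected in at least one sample-point (see module doc)."""
    keep = _detection_mask(m, cfg).any(axis=1)
    return m.subset(m.intensity.index[keep])


def filter_timeseries(m: ExpressionMatrix, cfg: FilterConfig) -> ExpressionMatrix:
    """Panel rule plus per-spot significance in at least one sample-point.

    The intensity rule and the significance rule are satisfied
    independently; they need not coincide at the same sample-point.
    """
    if cfg.sig_p is None:
        raise ValueError("timeseries filtering requires cfg.sig_p")
    if m.pvals is None:
        raise ValueError("expression matrix lacks per-spot p-values")
    keep = _detection_mask(m, cfg).any(axis=1) & (m.pvals < cfg.sig_p).any(axis=1)
    return m.subset(m.intensity.index[keep])


@dataclass
class RatioMatrix:
    """Genes x samples of log2 expression ratios, with (time, diet) labels."""

    ratios: pd.DataFrame
    meta: pd.DataFrame  # sample -> time (days), diet, replicate

    def __post_init__(self) -> None:
        missing = [s for s in self.ratios.columns if s not in self.meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing}")
        for col in ("time", "diet"):
            if col not in self.meta.columns:
                raise ValueError(f"metadata lacks {col!r} column")

    @property
    def times(self) -> list:
        return sorted(self.meta.loc[self.ratios.columns, "time"].unique())

    @property
    def diets(self) -> list:
        return sorted(self.meta.loc[self.ratios.columns, "diet"].unique())


@dataclass
class DietTimeResult:
    """Per (gene, time) diet contrast with BH-adjusted p-values.

    ``table`` columns: gene, time, estimate (log2 units, diet_b - diet_a
    with diets in sorted label order), se, df, p, p_adj.  Non-estimable
    contrasts (an empty cell) carry NaN rather than raising.
    """

    table: pd.DataFrame
    diet_a: str
    diet_b: str


def diet_within_time(r: RatioMatrix) -> DietTimeResult:
    """OLS cell-means model per gene: diet effect nested within time point.

    For each gene, every (time, diet) cell mean is a free parameter; the
    residual variance is pooled across cells, and for each time point the
    contrast mean(diet_b) - mean(diet_a) is tested two-sided against a t
    distribution with (n_obs - n_cells) degrees of freedom.  BH adjustment
    runs jointly over all gene x time tests.
    """
    meta = r.meta.loc[r.ratios.columns]
    diets = sorted(meta["diet"].unique())
    if len(diets) != 2:
        raise ValueError(f"expected exactly 2 diets, found {diets}")
    da, db = diets
    times = sorted(meta["time"].unique())
    cells = {
        (t, d): np.array([i for i, s in enumerate(r.ratios.columns)
                          if meta.loc[s, "time"] == t and meta.loc[s, "diet"] == d])
        for t in times for d in diets
    }
    X = r.ratios.to_numpy(dtype=float)
    rows = []
    for gi, gene in enumerate(r.ratios.index):
        y = X[gi]
        ss, n_obs, n_cells = 0.0, 0, 0
        means: dict[tuple, float] = {}
        counts: dict[tuple, int] = {}
        for key, idx in cells.items():
            vals = y[idx]
            vals = vals[~np.isnan(vals)]
            if len(vals) == 0:
                continue
            mu = vals.mean()
            means[key] = mu
            counts[key] = len(vals)
            ss += ((vals - mu) ** 2).sum()
            n_obs += len(vals)
            n_cells += 1
        df = n_obs - n_cells
        s2 = ss / df if df > 0 else np.nan
        for t in times:
            ka, kb = (t, da), (t, db)
            if ka not in means or kb not in means:
                rows.append((gene, t, np.nan, np.nan, df, np.nan))
                continue
            est = means[kb] - means[ka]
            se = np.sqrt(s2 * (1.0 / counts[ka] + 1.0 / counts[kb])) if df > 0 else np.nan
            if df > 0 and se > 0:
                p = 2.0 * stats.t.sf(abs(est) / se, df)
            elif df > 0 and se == 0:
                p = 0.0 if est != 0 else 1.0
            else:
                p = np.nan
            rows.append((gene, t, est, se, df, p))
    table = pd.DataFrame(rows, columns=["gene", "time", "estimate", "se", "df", "p"])
    table["p_adj"] = np.nan
    ok = table["p"].notna()
    if ok.any():
        table.loc[ok, "p_adj"] = multipletests(table.loc[ok, "p"], method="fdr_bh")[1]
    return DietTimeResult(table=table, diet_a=da, diet_b=db)


def mean_cluster_fold(
    r: RatioMatrix,
    cluster: list[str],
    times: list,
    diets: tuple[str, str] | None = None,
) -> float:
    """2**(mean log2 diet difference over the named times across a cluster).

    ``diets`` orders the difference (second minus first); default is sorted
    label order.  The magnitude is the fold change between diets for the
    cluster at those time points (e.g. 1.8 for a 1.8-fold difference).
    """
    if not cluster:
        raise ValueError("cluster is empty")
    meta = r.meta.loc[r.ratios.columns]
    if diets is None:
        ds = sorted(meta["diet"].unique())
        diets = (ds[0], ds[1])
    da, db = diets
    sel_a = [s for s in r.ratios.columns
             if meta.loc[s, "time"] in set(times) and meta.loc[s, "diet"] == da]
    sel_b = [s for s in r.ratios.columns
             if meta.loc[s, "time"] in set(times) and meta.loc[s, "diet"] == db]
    if not sel_a or not sel_b:
        raise ValueError(f"no data at times {times} for both diets")
    genes = [g for g in r.ratios.index if g in set(cluster)]
    diff = (
        r.ratios.loc[genes, sel_b].mean(axis=1)
        - r.ratios.loc[genes, sel_a].mean(axis=1)
    ).mean()
    return float(2.0 ** diff)


def write_expression(m: ExpressionMatrix, prefix) -> None:
    """Write intensity/present/pvals as parallel TSVs plus metadata."""
    m.intensity.to_csv(f"{prefix}_expr.tsv", sep="\t")
    m.meta.to_csv(f"{prefix}_meta.tsv", sep="\t")
    m.present.astype(int).to_csv(f"{prefix}_present.tsv", sep="\t")
    if m.pvals is not None:
        m.pvals.to_csv(f"{prefix}_pvals.tsv", sep="\t")
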