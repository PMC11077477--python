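"""Whole-brain FOS region statistics.

Counts of FOS+ cells per atlas region, collected across samples (animals) that
belong to experimental conditions (saline / drug), processing batches, and
exposure phases (acute, withdrawal, chronic), are the substrate here.  The
analyses are:

* batch-wise z-scoring of counts (each region normalized within its batch),
* a one-way ANOVA screen across conditions with k-means phenotyping of the
  surviving regions,
* per-drug contrasts against saline with a shared/specific classification, and
* Euclidean similarity of saline-normalized response profiles across exposure
  phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import InvalidInputError

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ["sample", "condition", "batch", "phase"]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class RegionTable:
    """Region x sample matrix of FOS+ counts (or z-scores) with sample labels.

    Parameters
    ----------
    regions
        Ordered, unique atlas acronyms (row labels).
    samples
        One row per sample column of ``values``; columns
        ``sample, condition, batch, phase``.
    values
        ``(n_regions, n_samples)`` array.  Nonnegative when ``scale='counts'``.
    scale
        One of ``{"counts", "zscore", "saline-subtracted"}``.
    flags
        Free-form QC annotations, e.g. zero-variance (region, batch) pairs.
    """

    regions: list[str]
    samples: pd.DataFrame
    values: np.ndarray
    scale: str = "counts"
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.regions) != len(set(self.regions)):
            raise InvalidInputError("duplicate region names")
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise InvalidInputError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.regions)} regions x {len(self.samples)} samples"
            )
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise InvalidInputError(f"sample table missing columns {missing}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("non-finite values in region table")
        if self.scale == "counts" and np.any(self.values < 0):
            raise InvalidInputError("negative counts in region table")

    # -- long-format CSV interchange (region,sample,condition,batch,phase,count)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for j, meta in self.samples.reset_index(drop=True).iterrows():
            for i, region in enumerate(self.regions):
                rows.append(
                    (region, meta["sample"], meta["condition"], meta["batch"],
                     meta["phase"], self.values[i, j])
                )
        return pd.DataFrame(
            rows, columns=["region", "sample", "condition", "batch", "phase", "count"]
        )

    @classmethod
    def from_long(cls, df: pd.DataFrame, scale: str = "counts") -> "RegionTable":
        regions = list(dict.fromkeys(df["region"]))
        meta = (
            df.drop_duplicates("sample")[SAMPLE_COLUMNS]
            .reset_index(drop=True)
        )
        wide = df.pivot(index="region", columns="sample", values="count")
        wide = wide.loc[regions, list(meta["sample"])]
        return cls(regions, meta, wide.to_numpy(dtype=float), scale=scale)


@dataclass
class RegionVector:
    """A per-region scalar vector (e.g. a saline-subtracted FOS contrast)."""

    regions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.regions) != len(set(self.regions)):
            raise InvalidInputError("duplicate region names in vector")
        if len(self.regions) != self.values.shape[0]:
            raise InvalidInputError("region/value length mismatch")


@dataclass
class PhaseProfile:
    """(acute, withdrawal, chronic) saline-normalized z-scores for one region."""

    region: str
    drug: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (3,):
            raise InvalidInputError("phase profile must have exactly 3 values")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def zscore_by_batch(table: RegionTable) -> RegionTable:
    """Z-score each region within each batch, across that batch's samples.

    Uses the sample standard deviation (ddof=1).  A (region, batch) cell set
    with zero variance maps to z=0 and is recorded in ``flags['zero_variance']``
    so downstream matrix operations stay total.
    """
    batches = table.samples["batch"].to_numpy()
    out = np.empty_like(table.values)
    zero_var: list[tuple[str, object]] = []
    for b in pd.unique(batches):
        cols = np.flatnonzero(batches == b)
        if cols.size < 2:
            raise InvalidInputError(f"batch {b!r} has fewer than 2 samples")
        block = table.values[:, cols]
        mu = block.mean(axis=1, keepdims=True)
        sd = block.std(axis=1, ddof=1, keepdims=True)
        flat = sd[:, 0] == 0
        sd[flat] = 1.0  # placeholder; those rows become exactly 0
        out[:, cols] = (block - mu) / sd
        out[np.flatnonzero(flat)[:, None], cols] = 0.0
        for i in np.flatnonzero(flat):
            zero_var.append((table.regions[i], b))
    if zero_var:
        logger.warning("zero-variance (region, batch) cells set to z=0: %s", zero_var)
    flags = dict(table.flags)
    if zero_var:
        flags["zero_variance"] = zero_var
    return RegionTable(
        list(table.regions), table.samples.copy(), out, scale="zscore", flags=flags
    )


def significant_region_clusters(
    table: RegionTable,
    alpha: float = 0.05,
    k: int | None = None,
    restarts: int = 25,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """ANOVA screen across conditions, then k-means on surviving region profiles.

    For each region a one-way ANOVA across condition groups is computed on the
    z-scored values; regions with unadjusted p < ``alpha`` are retained.  Their
    condition-mean profiles are clustered with seeded, multi-restart k-means.
    ``k=None`` selects k in 2..10 by silhouette score.

    Returns
    -------
    retained : DataFrame with columns ``region, p_anova, cluster``
    centroids : (k, n_conditions) array (empty if nothing retained)
    """
    if table.scale != "zscore":
        raise InvalidInputError("significant_region_clusters expects z-scored table")
    conds = table.samples["condition"].to_numpy()
    levels = pd.unique(conds)
    if len(levels) < 2:
        raise InvalidInputError("need at least 2 conditions")
    groups = [np.flatnonzero(conds == c) for c in levels]
    if any(g.size < 2 for g in groups):
        raise InvalidInputError("each condition needs at least 2 samples")

    pvals = np.array(
        [stats.f_oneway(*(table.values[i, g] for g in groups)).pvalue
         for i in range(len(table.regions))]
    )
    # constant-everywhere regions yield NaN F; they cannot be significant
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    keep = np.flatnonzero(pvals < alpha)
    if keep.size == 0:
        empty = pd.DataFrame(columns=["region", "p_anova", "cluster"])
        return empty, np.empty((0, len(levels)))

    profiles = np.column_stack(
        [table.values[np.ix_(keep, g)].mean(axis=1) for g in groups]
    )
    if k is not None and k > keep.size:
        raise InvalidInputError(f"k={k} exceeds {keep.size} retained regions")
    if k is None:
        best = (-np.inf, 2, None)
        for kk in range(2, min(10, keep.size - 1) + 1):
            km = KMeans(n_clusters=kk, n_init=restarts, random_state=seed).fit(profiles)
            if len(set(km.labels_)) < 2:
                continue
            s = silhouette_score(profiles, km.labels_)
            if s > best[0]:
                best = (s, kk, km)
        km = best[2]
        if km is None:  # < 3 retained regions: a single cluster
            km = KMeans(n_clusters=1, n_init=restarts, random_state=seed).fit(profiles)
    else:
        km = KMeans(n_clusters=k, n_init=restarts, random_state=seed).fit(profiles)

    retained = pd.DataFrame(
        {
            "region": [table.regions[i] for i in keep],
            "p_anova": pvals[keep],
            "cluster": km.labels_,
        }
    )
    return retained, km.cluster_centers_


def drug_contrast(
    table: RegionTable,
    saline_label: str = "saline",
    alpha: float = 0.05,
) -> tuple[dict[str, RegionVector], dict[str, str]]:
    """Per-drug saline-subtracted mean-z vectors and shared/specific classes.

    For each non-saline condition d, the contrast vector is
    ``mean z(d) - mean z(saline)`` per region.  Per region, a Welch two-sample
    t-test of each drug against saline at p < ``alpha`` determines the class:
    significant under every drug -> ``"common"``; under exactly one ->
    ``"<drug>-specific"``; otherwise ``"none"``.
    """
    conds = table.samples["condition"].to_numpy()
    if saline_label not in conds:
        raise InvalidInputError(f"missing condition {saline_label!r}")
    drugs = [c for c in pd.unique(conds) if c != saline_label]
    if not drugs:
        raise InvalidInputError("no drug condition present")
    sal = np.flatnonzero(conds == saline_label)

    vectors: dict[str, RegionVector] = {}
    sig: dict[str, np.ndarray] = {}
    for d in drugs:
        cols = np.flatnonzero(conds == d)
        if cols.size == 0:
            raise InvalidInputError(f"missing condition {d!r}")
        delta = table.values[:, cols].mean(axis=1) - table.values[:, sal].mean(axis=1)
        vectors[d] = RegionVector(list(table.regions), delta)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = stats.ttest_ind(
                table.values[:, cols], table.values[:, sal],
                axis=1, equal_var=False,
            ).pvalue
        sig[d] = np.where(np.isnan(p), 1.0, p) < alpha

    classes: dict[str, str] = {}
    for i, region in enumerate(table.regions):
        hits = [d for d in drugs if sig[d][i]]
        if len(hits) == len(drugs) and len(drugs) >= 2:
            classes[region] = "common"
        elif len(hits) == 1:
            classes[region] = f"{hits[0]}-specific"
        else:
            classes[region] = "none"
    return vectors, classes


def phase_similarity(a: PhaseProfile, b: PhaseProfile) -> float:
    """Euclidean distance between two saline-normalized 3-phase profiles."""
    if a.region != b.region:
        raise InvalidInputError(
            f"phase profiles for different regions: {a.region!r} vs {b.region!r}"
        )
    return float(np.linalg.norm(a.values - b.values))
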