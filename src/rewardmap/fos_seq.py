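"""FOS-Seq: screening genes whose regional expression tracks FOS activity.

A saline-subtracted, brain-wide FOS contrast vector is matched region-by-region
against an in situ hybridization (ISH) expression atlas.  Both the FOS vector
and every gene's expression vector are sigmoid transformed (logistic applied to
standardized values, damping outlier leverage), Pearson-correlated per gene,
and the resulting coefficient distribution is calibrated against a fitted
Gaussian null.  Genes beyond +/- one fitted sigma with a BH-adjusted p below
alpha are called positively / negatively correlated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from scipy.special import expit
from statsmodels.stats.multitest import multipletests

from .errors import InvalidInputError
from .fos_mapping import RegionVector

logger = logging.getLogger(__name__)

MIN_STABLE_REGIONS = 10  # below this, per-gene correlations are unstable


@dataclass
class IshAtlas:
    """Gene x region expression-energy matrix on a fixed region vocabulary."""

    genes: list[str]
    regions: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise InvalidInputError("duplicate gene symbols in atlas")
        if self.values.shape != (len(self.genes), len(self.regions)):
            raise InvalidInputError("atlas shape mismatch")


@dataclass
class FosSeqRecord:
    gene: str
    r: float
    p: float
    p_adj: float = np.nan
    cls: str = "none"


@dataclass
class NullModel:
    """Gaussian null of the PCC histogram; threshold defaults to 1 sigma."""

    mu: float
    sigma: float
    threshold: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.threshold <= 0:
            raise InvalidInputError("null model requires sigma > 0, threshold > 0")


def match_regions(
    fos: RegionVector, atlas: IshAtlas
) -> tuple[RegionVector, IshAtlas]:
    """Restrict FOS vector and atlas to their shared regions, sorted lexically."""
    if not fos.regions or not atlas.regions:
        raise InvalidInputError("empty region set")
    shared = sorted(set(fos.regions) & set(atlas.regions))
    if not shared:
        raise InvalidInputError("no shared regions between FOS vector and atlas")
    dropped_fos = sorted(set(fos.regions) - set(shared))
    dropped_atlas = sorted(set(atlas.regions) - set(shared))
    if dropped_fos or dropped_atlas:
        logger.info(
            "match_regions dropped %d FOS / %d atlas regions",
            len(dropped_fos), len(dropped_atlas),
        )
    if len(shared) < MIN_STABLE_REGIONS:
        logger.warning(
            "only %d shared regions; per-gene correlations will be unstable",
            len(shared),
        )
    fidx = {r: i for i, r in enumerate(fos.regions)}
    aidx = {r: i for i, r in enumerate(atlas.regions)}
    fos_out = RegionVector(shared, fos.values[[fidx[r] for r in shared]])
    atlas_out = IshAtlas(
        list(atlas.genes), shared, atlas.values[:, [aidx[r] for r in shared]]
    )
    return fos_out, atlas_out


def sigmoid_transform(v: RegionVector) -> RegionVector:
    """Standardize (ddof=1) then apply the logistic function.

    Strictly order-preserving; output in (0, 1); a value at the input mean maps
    to exactly 0.5.
    """
    x = v.values
    sd = x.std(ddof=1)
    if x.shape[0] < 2 or sd == 0:
        raise InvalidInputError("sigmoid_transform requires >= 2 distinct values")
    return RegionVector(list(v.regions), expit((x - x.mean()) / sd))


def fosseq_pcc(fos_t: RegionVector, gene_t: RegionVector) -> tuple[float, float]:
    """Pearson r between transformed vectors, with the exact t-based p (n-2 df)."""
    if fos_t.values.shape != gene_t.values.shape:
        raise InvalidInputError("mismatched vector lengths")
    n = fos_t.values.shape[0]
    if n < 4:
        raise InvalidInputError("need at least 4 aligned regions")
    res = stats.pearsonr(fos_t.values, gene_t.values)
    return float(res.statistic), float(res.pvalue)


def fit_null(
    pccs: np.ndarray,
    method: str = "moments",
    fixed_threshold: float | None = None,
) -> NullModel:
    """Fit a Gaussian null to the screen-wide PCC distribution.

    ``method="moments"`` is the Gaussian MLE (sample mean / sd); ``"histogram"``
    least-squares fits a Gaussian density to a Freedman-Diaconis histogram.
    The classification threshold is the fitted sigma rounded to 2 decimals
    unless ``fixed_threshold`` overrides it.
    """
    r = np.asarray(pccs, dtype=float)
    if r.size < 100:
        raise InvalidInputError("fit_null requires at least 100 PCCs")
    if np.ptp(r) == 0:
        raise InvalidInputError("PCC sample has zero spread")
    if method == "moments":
        mu, sigma = float(r.mean()), float(r.std(ddof=1))
    elif method == "histogram":
        counts, edges = np.histogram(r, bins="fd", density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])

        def gauss(x, m, s):
            return np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))

        (mu, sigma), _ = optimize.curve_fit(
            gauss, centers, counts, p0=(r.mean(), r.std(ddof=1))
        )
        mu, sigma = float(mu), float(abs(sigma))
    else:
        raise InvalidInputError(f"unknown null_fit method {method!r}")
    if fixed_threshold is not None:
        threshold = float(fixed_threshold)
    else:
        threshold = round(sigma, 2)
        if threshold == 0:  # sigma below rounding resolution
            threshold = sigma
    return NullModel(mu=mu, sigma=sigma, threshold=threshold)


def classify_genes(
    records: list[FosSeqRecord], null: NullModel, alpha: float = 0.05
) -> list[FosSeqRecord]:
    """BH-adjust p-values over the whole screen and call gene classes.

    positive: r > +threshold and p_adj < alpha; negative: r < -threshold and
    p_adj < alpha; otherwise none.
    """
    if not records:
        return []
    p = np.array([rec.p for rec in records])
    p_adj = multipletests(p, method="fdr_bh")[1]
    out = []
    for rec, pa in zip(records, p_adj):
        if rec.r > null.threshold and pa < alpha:
            cls = "positive"
        elif rec.r < -null.threshold and pa < alpha:
            cls = "negative"
        else:
            cls = "none"
        out.append(FosSeqRecord(rec.gene, rec.r, rec.p, float(pa), cls))
    return out


def fosseq_screen(
    fos: RegionVector,
    atlas: IshAtlas,
    alpha: float = 0.05,
    fixed_threshold: float | None = None,
    null_fit: str = "moments",
) -> tuple[list[FosSeqRecord], NullModel]:
    """Run the full screen: match, transform, correlate, calibrate, classify."""
    fos_m, atlas_m = match_regions(fos, atlas)
    fos_t = sigmoid_transform(fos_m)
    records = []
    for g, row in zip(atlas_m.genes, atlas_m.values):
        gene_t = sigmoid_transform(RegionVector(list(atlas_m.regions), row))
        r, p = fosseq_pcc(fos_t, gene_t)
        records.append(FosSeqRecord(g, r, p))
    null = fit_null(
        np.array([rec.r for rec in records]),
        method=null_fit,
        fixed_threshold=fixed_threshold,
    )
    return classify_genes(records, null, alpha=alpha), null


def shared_genes(
    res_a: list[FosSeqRecord], res_b: list[FosSeqRecord]
) -> dict[str, list[tuple[str, float, float]]]:
    """Intersect two screens: genes significant in both, by sign quadrant.

    Quadrants are keyed "++", "+-", "-+", "--" (sign in screen a, then b);
    within each, genes are ranked by min(|r_a|, |r_b|) descending.
    """
    b_by_gene = {rec.gene: rec for rec in res_b}
    universe_overlap = set(rec.gene for rec in res_a) & set(b_by_gene)
    if not universe_overlap:
        logger.warning("shared_genes: gene universes are disjoint")
        return {q: [] for q in ("++", "+-", "-+", "--")}
    sign = {"positive": "+", "negative": "-"}
    quadrants: dict[str, list[tuple[str, float, float, float]]] = {
        q: [] for q in ("++", "+-", "-+", "--")
    }
    for ra in res_a:
        rb = b_by_gene.get(ra.gene)
        if rb is None or ra.cls == "none" or rb.cls == "none":
            continue
        q = sign[ra.cls] + sign[rb.cls]
        quadrants[q].append((ra.gene, ra.r, rb.r, min(abs(ra.r), abs(rb.r))))
    return {
        q: [(g, ra, rb) for g, ra, rb, _ in
            sorted(entries, key=lambda t: (-t[3], t[0]))]
        for q, entries in quadrants.items()
    }
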