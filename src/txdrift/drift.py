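"""Transcriptional drift and drift-variance.

Transcriptional drift (td) of a gene at age t is its log-fold change in
expression relative to a "young reference" profile,

    td_g(t) = log( (cpm_g(t) + c) / (ref_g + c) )

with a small pseudocount c guarding residual zeros.  Drift-variance (dv) of a
group of n drift values is their n-1-denominator sample variance,

    dv = 1/(n-1) * sum_i (td_i - mean(td))^2 .

A young transcriptome has td ~ 0 for every gene and hence small dv; as genes
drift up and down in opposing directions with age, dv grows.  dv is therefore
a transcriptome-intrinsic metric of how far a sample has moved from the
young-adult co-expression pattern, distinct from transcriptional noise
(variance of one gene across replicates).

Two ways to build the reference from replicated young samples:

* ``pooled_mean`` averages all young replicates per gene.  Robust, but the
  young age group then references itself, so its (too small) dv must never
  enter statistical comparisons; the API flags those groups non-testable.
* ``holdout`` sets aside one or more young samples as the reference.  The
  remaining young replicates yield an honest young dv; the held-out samples
  are dropped from all downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import DataError, ExpressionMatrix, GeneSet, SampleAnnotation


@dataclass
class YoungReference:
    """Per-gene reference expression on the cpm scale."""

    ref_expression: pd.Series  # index: gene ids, values: cpm
    method: Literal["pooled_mean", "holdout"]
    ref_age: float
    source_sample_ids: list[str]
    detected_all: pd.Series  # True where gene nonzero in every source sample

    @property
    def excluded_sample_ids(self) -> list[str]:
        """Samples that must not appear downstream (holdout method only)."""
        return list(self.source_sample_ids) if self.method == "holdout" else []


@dataclass
class DriftMatrix:
    """Per-gene drift values for a set of samples, with provenance."""

    gene_ids: list[str]
    sample_ids: list[str]
    td: np.ndarray  # genes x samples
    log_base: float
    reference: YoungReference
    pseudocount: float

    def __post_init__(self) -> None:
        self.td = np.asarray(self.td, dtype=float)
        if not np.isfinite(self.td).all():
            raise DataError("non-finite drift values; check pseudocount/filter policy")

    @property
    def self_referential_sample_ids(self) -> list[str]:
        """Samples whose td is circular (they helped build a pooled_mean reference)."""
        if self.reference.method == "pooled_mean":
            return [s for s in self.sample_ids if s in set(self.reference.source_sample_ids)]
        return []

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.td, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class TukeySummary:
    whisker_lo: float
    q1: float
    median: float
    q3: float
    whisker_hi: float


@dataclass
class DriftVarianceResult:
    """Drift-variance of one sample group, with box-plot bookkeeping.

    ``variance`` is always computed over all ``n_values`` drift values;
    outliers beyond the 1.5*IQR whiskers are counted for display purposes
    only and never removed from the statistic.
    """

    group_label: str
    n_values: int
    variance: float
    mean_td: float
    tukey: TukeySummary
    n_outliers_omitted_for_plot: int
    self_referential: bool = False
    sample_ids: list[str] = field(default_factory=list)


def build_young_reference(
    m: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    ref_age: float,
    method: Literal["pooled_mean", "holdout"] = "pooled_mean",
    holdout_ids: Sequence[str] | None = None,
    ref_age_is_max: bool = False,
) -> YoungReference:
    """Construct the young reference profile from samples at ``ref_age``.

    ``pooled_mean`` uses every sample at the reference age; ``holdout`` uses
    only ``holdout_ids`` (default: the first reference-age sample in
    annotation order, a deterministic choice) and marks them excluded.
    With ``ref_age_is_max`` the reference pool is every sample aged at most
    ``ref_age`` — for designs whose young samples span a range of ages
    rather than one harvest day.
    """
    if m.unit != "cpm":
        raise DataError("young reference must be built from a cpm matrix")
    by_id = {a.sample_id: a for a in annotations}
    missing = [s for s in m.sample_ids if s not in by_id]
    if missing:
        raise DataError(f"samples without annotation: {missing[:5]}")
    if ref_age_is_max:
        ref_samples = [s for s in m.sample_ids if by_id[s].age <= ref_age]
    else:
        ref_samples = [s for s in m.sample_ids if by_id[s].age == ref_age]
    if not ref_samples:
        raise DataError(f"no sample at reference age {ref_age}")
    if method == "pooled_mean":
        source = ref_samples
    elif method == "holdout":
        source = list(holdout_ids) if holdout_ids else ref_samples[:1]
        not_ref = [s for s in source if s not in set(ref_samples)]
        if not_ref:
            raise DataError(f"holdout samples not at reference age {ref_age}: {not_ref}")
    else:
        raise DataError(f"unknown reference method {method!r}")
    df = m.to_frame()[source]
    return YoungReference(
        ref_expression=df.mean(axis=1),
        method=method,
        ref_age=ref_age,
        source_sample_ids=source,
        detected_all=(df > 0).all(axis=1),
    )


def compute_drift(
    m: ExpressionMatrix,
    ref: YoungReference,
    log_base: float = 2,
    pseudocount: float = 0.5,
    min_detection: bool = True,
) -> DriftMatrix:
    """Per-gene log-fold drift of every sample relative to the young reference.

    Genes failing the minimum-detection filter (zero in any reference
    constituent sample, when ``min_detection``) are dropped, not imputed.
    Under the holdout method the reference samples themselves are dropped
    from the output.  ``log_base`` only rescales td by a constant; variance
    comparisons downstream are invariant to it.
    """
    if m.unit != "cpm":
        raise DataError("drift is computed on cpm matrices")
    if log_base <= 0 or log_base == 1:
        raise DataError(f"invalid log base {log_base}")
    if pseudocount < 0:
        raise DataError("pseudocount must be nonnegative")
    df = m.to_frame()
    keep_samples = [s for s in m.sample_ids if s not in set(ref.excluded_sample_ids)]
    df = df[keep_samples]

    shared = df.index.intersection(ref.ref_expression.index)
    if min_detection:
        shared = shared[ref.detected_all.reindex(shared).fillna(False).to_numpy(bool)]
    refvals = ref.ref_expression.reindex(shared).to_numpy(float)
    ok = (refvals + pseudocount) > 0
    shared, refvals = shared[ok], refvals[ok]
    if len(shared) == 0:
        raise DataError("no genes left after min-detection filtering")
    ratios = (df.loc[shared].to_numpy(float) + pseudocount) / (refvals[:, None] + pseudocount)
    if (ratios <= 0).any():
        raise DataError("zero expression with zero pseudocount; set pseudocount > 0")
    td = np.log(ratios) / math.log(log_base)
    return DriftMatrix(
        gene_ids=list(shared),
        sample_ids=keep_samples,
        td=td,
        log_base=log_base,
        reference=ref,
        pseudocount=pseudocount,
    )


def _tukey(values: np.ndarray) -> tuple[TukeySummary, int]:
    # type-7 (linear interpolation) quartiles; whiskers at the most extreme
    # points within 1.5*IQR of the box
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    summary = TukeySummary(
        whisker_lo=float(inside.min()),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        whisker_hi=float(inside.max()),
    )
    return summary, int(len(values) - len(inside))


def drift_variance(
    d: DriftMatrix,
    groups: Mapping[str, str],
    gene_set: GeneSet | None = None,
) -> list[DriftVarianceResult]:
    """Drift-variance per sample group, pooling td values over member samples.

    ``groups`` maps sample id to group label; samples absent from the mapping
    are ignored.  With ``gene_set`` the pooled values are restricted to the
    set's genes.  Groups containing samples that constitute a pooled-mean
    reference are flagged ``self_referential`` — their dv is an artifact of
    circular referencing and must not be used in statistical comparisons.
    """
    frame = d.to_frame()
    if gene_set is not None:
        keep = [g for g in d.gene_ids if g in set(gene_set.gene_ids)]
        if not keep:
            raise DataError(f"gene set {gene_set.name!r} shares no genes with the drift matrix")
        frame = frame.loc[keep]
    circular = set(d.self_referential_sample_ids)
    labels = list(dict.fromkeys(groups[s] for s in d.sample_ids if s in groups))
    results = []
    for label in labels:
        members = [s for s in d.sample_ids if groups.get(s) == label]
        if not members:
            raise DataError(f"group {label!r} has no member samples")
        pooled = frame[members].to_numpy(float).ravel()
        if len(pooled) < 2:
            raise DataError(f"group {label!r} pools fewer than 2 drift values")
        tukey, n_out = _tukey(pooled)
        results.append(
            DriftVarianceResult(
                group_label=label,
                n_values=int(len(pooled)),
                variance=float(np.var(pooled, ddof=1)),
                mean_td=float(pooled.mean()),
                tukey=tukey,
                n_outliers_omitted_for_plot=n_out,
                self_referential=bool(circular & set(members)),
                sample_ids=members,
            )
        )
    return results


def bin_samples(
    annotations: Sequence[SampleAnnotation],
    bin_edges: Sequence[float],
    labels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assign samples to half-open age bins ``[e_i, e_{i+1})``.

    Ages at or above the last edge fall into an overflow bin; an age below
    the first edge is an error rather than a silent drop.  Labels default to
    the interval notation derived from the edges.
    """
    edges = [float(e) for e in bin_edges]
    if sorted(set(edges)) != edges:
        raise DataError("bin edges must be strictly increasing")
    if labels is None:
        labels = [f"[{edges[i]:g},{edges[i+1]:g})" for i in range(len(edges) - 1)]
        labels = list(labels) + [f">={edges[-1]:g}"]
    elif len(labels) != len(edges):
        raise DataError(f"need {len(edges)} labels (including overflow), got {len(labels)}")
    out: dict[str, str] = {}
    for a in annotations:
        if a.age < edges[0]:
            raise DataError(f"sample {a.sample_id!r}: age {a.age} below first bin edge {edges[0]}")
        idx = int(np.searchsorted(edges, a.age, side="right")) - 1
        out[a.sample_id] = labels[idx]
    return out


def subsample_genes(
    gene_ids: Sequence[str], n_sets: int, set_size: int, seed: int
) -> list[GeneSet]:
    """Partition a random draw of genes into disjoint equally sized sets."""
    if n_sets * set_size > len(gene_ids):
        raise DataError(
            f"cannot draw {n_sets} disjoint sets of {set_size} from {len(gene_ids)} genes"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(gene_ids), size=n_sets * set_size, replace=False)
    return [
        GeneSet(
            name=f"subsample_{i+1}",
            gene_ids=[gene_ids[j] for j in chosen[i * set_size : (i + 1) * set_size]],
            source=f"subsample(seed={seed})",
        )
        for i in range(n_sets)
    ]


def leading_logfc_mds(
    m: ExpressionMatrix,
    top_n: int = 500,
    n_dims: int = 2,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Leading log-fold-change sample distances with classical metric scaling.

    The distance between two samples is the root-mean-square of the ``top_n``
    largest absolute log2 fold-changes between them — the dominant axis of
    transcriptome divergence, computed pairwise.  Classical (Torgerson) MDS
    of that matrix gives low-dimensional coordinates; these are defined only
    up to rotation and reflection.

    Returns ``(coordinates, distances)`` as DataFrames indexed by sample id.
    """
    if m.unit != "cpm":
        raise DataError("leading_logfc_mds expects a cpm matrix")
    n = len(m.sample_ids)
    if n < 3:
        raise DataError("MDS needs at least 3 samples")
    if top_n < 1:
        raise DataError("top_n must be >= 1")
    if top_n > len(m.gene_ids):
        import warnings

        warnings.warn(
            f"top_n={top_n} exceeds the {len(m.gene_ids)}-gene universe; using all genes",
            stacklevel=2,
        )
        top_n = len(m.gene_ids)
    logx = np.log2(m.values + pseudocount)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            fc = np.abs(logx[:, i] - logx[:, j])
            top = np.partition(fc, len(fc) - top_n)[-top_n:]
            dist[i, j] = dist[j, i] = math.sqrt(float(np.mean(top**2)))
    # classical scaling: double-center the squared distances, eigendecompose
    j_mat = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j_mat @ (dist**2) @ j_mat
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1][:n_dims]
    coords = eigvec[:, order] * np.sqrt(np.clip(eigval[order], 0, None))
    return (
        pd.DataFrame(coords, index=m.sample_ids, columns=[f"dim{k+1}" for k in range(n_dims)]),
        pd.DataFrame(dist, index=m.sample_ids, columns=m.sample_ids),
    )


def drift_plot_table(results: Sequence[DriftVarianceResult]) -> pd.DataFrame:
    """Tidy one-row-per-group summary suitable for plotting and archival."""
    if not results:
        raise DataError("no drift-variance results to tabulate")
    return pd.DataFrame(
        {
            "group": [r.group_label for r in results],
            "n_values": [r.n_values for r in results],
            "variance": [r.variance for r in results],
            "mean_td": [r.mean_td for r in results],
            "whisker_lo": [r.tukey.whisker_lo for r in results],
            "q1": [r.tukey.q1 for r in results],
            "median": [r.tukey.median for r in results],
            "q3": [r.tukey.q3 for r in results],
            "whisker_hi": [r.tukey.whisker_hi for r in results],
            "n_outliers": [r.n_outliers_omitted_for_plot for r in results],
            "self_referential": [r.self_referential for r in results],
        }
    )
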