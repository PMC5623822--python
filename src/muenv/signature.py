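"""Microenvironment (muENV) signature construction, subtype gating, and scoring.

A muENV signature is the set of genes differentially expressed in cell lines
of one breast-cancer subtype after exposure to CAF- vs NAF-conditioned
medium, together with a reference centroid: the mean-centered mean expression
of those genes in the subtype's CAF-treated cell lines.  A clinical tumor is
scored by the Spearman correlation between its centered expression on the
signature genes and the centroid; tumors with rho strictly greater than 0 are
called microenvironment-positive.

Cohorts are gated into ER+/HER2-, HER2+ and ER-/HER2- subtypes from the
bimodal ESR1/ERBB2 reporter distributions before scoring; each signature is
applied only within its own subtype.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from sklearn.mixture import GaussianMixture

from .core_io import ExperimentDesign, ExpressionMatrix

logger = logging.getLogger("muenv")

__all__ = [
    "MuEnvSignature",
    "MuEnvCall",
    "SubtypeThresholds",
    "BimodalFit",
    "mean_center",
    "build_signature",
    "spearman_rho",
    "classify_muenv",
    "bimodal_threshold",
    "assign_subtype",
]


@dataclass
class MuEnvSignature:
    """Subtype-specific signature: DE genes plus the CAF-treated centroid."""

    subtype: str
    genes: list[tuple[str, str]]  # (gene_id, "up"/"down")
    centroid: dict[str, float]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature has no genes")
        if set(self.centroid) != {g for g, _ in self.genes}:
            raise ValueError("centroid keys differ from signature gene ids")

    def to_tsv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            fh.write("gene_id\tdirection\tcentroid_value\n")
            for gene, direction in self.genes:
                fh.write(f"{gene}\t{direction}\t{self.centroid[gene]:.10g}\n")
        with open(path + ".json", "w") as fh:
            json.dump({"subtype": self.subtype, **self.provenance}, fh, indent=1,
                      sort_keys=True)

    @classmethod
    def from_tsv(cls, path: str) -> "MuEnvSignature":
        table = pd.read_csv(path, sep="\t")
        genes = list(zip(table["gene_id"], table["direction"]))
        centroid = dict(zip(table["gene_id"], table["centroid_value"]))
        try:
            with open(path + ".json") as fh:
                prov = json.load(fh)
            subtype = prov.pop("subtype", "")
        except FileNotFoundError:
            prov, subtype = {}, ""
        return cls(subtype, genes, centroid, prov)


@dataclass
class MuEnvCall:
    """Per-sample Spearman rho against a signature centroid and the dichotomy."""

    table: pd.DataFrame  # index sample_id; columns rho, status, n_genes_used

    def positive_rate(self) -> float:
        return float((self.table["status"] == "positive").mean())

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index_label="sample_id",
                          float_format="%.10g")


@dataclass
class SubtypeThresholds:
    """ESR1/ERBB2 reporter rows and expression cuts for subtype gating."""

    esr1_reporter: str = "ESR1"
    erbb2_reporter: str = "ERBB2"
    esr1_cut: float = 0.0
    erbb2_cut: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.esr1_cut) and np.isfinite(self.erbb2_cut)):
            raise ValueError("subtype cuts must be finite")


@dataclass
class BimodalFit:
    """Two-component mixture threshold with a bimodality-strength score."""

    threshold: float
    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    strength: float  # |mu2 - mu1| / pooled sd


def mean_center(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract from each gene its mean across all samples of the collection."""
    if matrix.shape[1] < 2:
        raise ValueError("mean centering requires at least 2 samples")
    values = matrix.values.sub(matrix.values.mean(axis=1), axis=0)
    return ExpressionMatrix(values, matrix.detection_p, matrix.platform_tag)


def build_signature(
    de: Iterable[tuple[str, str]],
    centered_matrix: ExpressionMatrix,
    design: ExperimentDesign,
    subtype: str,
    provenance: dict | None = None,
) -> MuEnvSignature:
    """Build a signature from DE genes and the centered cell-line collection.

    ``centered_matrix`` must be the full cell-line collection after
    :func:`mean_center` (centered across all arrays of the platform).  The
    centroid is the mean of the subtype's CAF_CM samples on each DE gene.
    """
    genes = sorted(de)
    if not genes:
        raise ValueError("no genes pass thresholds: cannot build a signature")
    missing = [g for g, _ in genes if g not in centered_matrix.values.index]
    if missing:
        raise ValueError(f"DE genes absent from matrix: {missing}")
    caf_samples = design.samples(subtype=subtype, condition="CAF_CM")
    if not caf_samples:
        raise ValueError(f"no CAF_CM samples of subtype {subtype!r}")
    sub = centered_matrix.values.loc[[g for g, _ in genes], caf_samples]
    centroid = {g: float(m) for (g, _), m in zip(genes, sub.mean(axis=1))}
    return MuEnvSignature(subtype, genes, centroid, provenance or {})


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation (Pearson on average-tie ranks).

    Raises on constant input, where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def classify_muenv(
    centered_cohort: ExpressionMatrix,
    sig: MuEnvSignature,
    min_overlap: int = 10,
) -> MuEnvCall:
    """Score every sample against the signature centroid and dichotomize.

    Rank-based, so invariant to any strictly increasing transform of a
    sample's centered expression.  A sample whose expression is constant on
    the overlap genes (rho undefined) is reported negative with a warning
    rather than dropped, keeping cohort partitions complete.
    """
    overlap = [g for g, _ in sig.genes if g in centered_cohort.values.index]
    if len(overlap) < min_overlap:
        missing = sorted({g for g, _ in sig.genes} - set(overlap))
        raise ValueError(
            f"signature overlap {len(overlap)} below minimum {min_overlap}; "
            f"missing genes: {missing}"
        )
    centroid_vec = np.array([sig.centroid[g] for g in overlap])
    expr = centered_cohort.values.loc[overlap]
    records = []
    for sample in expr.columns:
        vec = expr[sample].to_numpy()
        try:
            rho = spearman_rho(centroid_vec, vec)
        except ValueError:
            warnings.warn(
                f"sample {sample}: constant expression on signature genes; "
                "rho undefined, reported negative",
                stacklevel=2,
            )
            rho = float("nan")
        status = "positive" if rho > 0 else "negative"
        records.append((sample, rho, status, len(overlap)))
    table = pd.DataFrame(
        records, columns=["sample_id", "rho", "status", "n_genes_used"]
    ).set_index("sample_id")
    return MuEnvCall(table)


def bimodal_threshold(values: np.ndarray, seed: int = 0, n_init: int = 10) -> BimodalFit:
    """Threshold a bimodal expression distribution via a 2-component mixture.

    EM (k = 2, ``n_init`` random restarts) is fit to the values; the threshold
    is the point between the component means where posterior membership
    crosses 0.5.  The fit is rejected as degenerate when a component weight
    drops below 0.02, when a single Gaussian explains the data at least as
    well (BIC), or when the component means are separated by less than one
    pooled standard deviation — EM happily splits a unimodal sample into two
    overlapping components, which is no basis for a threshold.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 20:
        raise ValueError("need at least 20 values for a mixture threshold")
    X = values.reshape(-1, 1)
    gm = GaussianMixture(
        n_components=2, n_init=n_init, random_state=seed, covariance_type="full"
    ).fit(X)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    if gm.bic(X) >= gm1.bic(X):
        raise ValueError(
            "degenerate mixture fit (one component explains the data as well; "
            "BIC k=2 >= k=1): distribution not bimodal, set the threshold manually"
        )
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.ravel())
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    m1, m2 = means[order]
    s1, s2 = sds[order]
    w1, w2 = weights[order]
    pooled = float(np.sqrt(w1 * s1**2 + w2 * s2**2))
    strength = float((m2 - m1) / pooled) if pooled > 0 else float("inf")
    if min(w1, w2) < 0.02 or strength < 1.0:
        raise ValueError(
            "degenerate mixture fit (weights "
            f"{w1:.3f}/{w2:.3f}, separation {strength:.2f} pooled sd): "
            "distribution not clearly bimodal, set the threshold manually"
        )

    def posterior_diff(v: float) -> float:
        logp1 = np.log(w1) + stats.norm.logpdf(v, m1, s1)
        logp2 = np.log(w2) + stats.norm.logpdf(v, m2, s2)
        return logp1 - logp2

    if posterior_diff(m1) <= 0 or posterior_diff(m2) >= 0:
        threshold = float((m1 + m2) / 2)  # pathological overlap; midpoint
    else:
        threshold = float(brentq(posterior_diff, m1, m2))
    return BimodalFit(threshold, (float(m1), float(m2)), (float(s1), float(s2)),
                      (float(w1), float(w2)), strength)


def assign_subtype(
    cohort: ExpressionMatrix, th: SubtypeThresholds
) -> pd.Series:
    """Partition cohort samples into luminal / her2 / basal from reporter rows.

    ERBB2 above its cut wins regardless of ESR1 (HER2+ tumors may be ER+ or
    ER-); otherwise ESR1 above its cut gives ER+/HER2- (luminal), and tumors
    below both cuts are ER-/HER2- (basal-like).  Exhaustive and disjoint.
    """
    for reporter in (th.esr1_reporter, th.erbb2_reporter):
        if reporter not in cohort.values.index:
            raise ValueError(f"reporter row {reporter!r} missing from cohort matrix")
    esr1 = cohort.values.loc[th.esr1_reporter]
    erbb2 = cohort.values.loc[th.erbb2_reporter]
    out = pd.Series(
        np.where(erbb2 > th.erbb2_cut, "her2",
                 np.where(esr1 > th.esr1_cut, "luminal", "basal")),
        index=cohort.values.columns,
        name="subtype",
    )
    return out
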