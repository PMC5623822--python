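"""Class comparison of CAF-CM vs NAF-CM treated cell lines within a subtype.

Per gene, a linear model ``expression ~ condition + cell_line`` is fit over
the subtype's CAF_CM and NAF_CM samples (serum-free controls are excluded
from the signature contrast; cell line enters as a fixed blocking factor).
Gene-wise residual variances are shrunk toward a common prior by the
empirical-Bayes hierarchical model: s2 ~ s0^2 * chi2_{d0} scaled, giving the
posterior variance

    s_tilde^2 = (d0 * s0^2 + dg * s2) / (d0 + dg)

and the moderated t-statistic t = log2fc / (s_tilde * c), referred to a t
distribution on d0 + dg degrees of freedom; c is the contrast's standard-
error multiplier from the design matrix.  The prior (d0, s0^2) is estimated
by matching the mean and variance of log s2 to their theoretical digamma /
trigamma expressions, with the trigamma equation inverted numerically.

DE calling uses the dual threshold: two-tailed p < 1e-4 and fold change
outside (0.67, 1.5), both strict, on the natural FC scale.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats

from .core_io import ExperimentDesign, ExpressionMatrix

logger = logging.getLogger("muenv")

__all__ = [
    "ContrastResult",
    "DEThresholds",
    "fit_linear_contrast",
    "moderated_t",
    "call_de",
    "estimate_variance_prior",
]

#: d0 estimates above this are reported as effectively infinite.
_D0_CLIP = (0.1, 1e6)
_D0_INFINITE = 1e5
#: floor applied to zero-variance genes
_VAR_FLOOR = 1e-12


@dataclass
class ContrastResult:
    """Per-gene statistics of the CAF-vs-NAF contrast plus the global prior."""

    table: pd.DataFrame  # index gene_id; log2fc, avg_expr, s2, df_residual, t_mod, p
    d0: float
    s0_sq: float
    subtype: str = ""

    @property
    def df_total(self) -> pd.Series:
        return self.d0 + self.table["df_residual"]

    def ranked_genes(self) -> list[tuple[str, float]]:
        """Gene list ranked by moderated t, descending; ties broken by gene id."""
        t = self.table["t_mod"]
        order = sorted(t.index, key=lambda g: (-t[g], g))
        return [(g, float(t[g])) for g in order]

    def to_tsv(self, path: str, thresholds: "DEThresholds | None" = None) -> None:
        out = self.table.copy()
        out["fc"] = np.exp2(out["log2fc"])
        if thresholds is not None:
            de = call_de(self, thresholds)
            flags = {g: d for g, d in de}
            out["de_flag"] = [int(g in flags) for g in out.index]
            out["direction"] = [flags.get(g, "") for g in out.index]
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


@dataclass
class DEThresholds:
    """Dual DE threshold: strict p cut and strict natural-scale FC gates."""

    p_cut: float = 1e-4
    fc_low: float = 0.67
    fc_high: float = 1.5

    def __post_init__(self) -> None:
        if not 0 < self.fc_low < 1 < self.fc_high:
            raise ValueError("need 0 < fc_low < 1 < fc_high")
        if not 0 < self.p_cut < 1:
            raise ValueError("p_cut must lie in (0,1)")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Method-of-moments estimate of (d0, s0^2) from gene-wise variances.

    Matches mean and variance of log s2 to the theoretical values under the
    scaled-chi-square sampling model.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = np.maximum(s2, _VAR_FLOOR)
    z = np.log(s2)
    e = z - float(special.digamma(dg / 2)) + math.log(dg / 2)
    n = len(e)
    evar = float(np.mean((e - e.mean()) ** 2) * n / (n - 1)) - float(
        special.polygamma(1, dg / 2)
    )
    if evar <= 0:
        # observed log-variances no more dispersed than chi-square sampling
        # alone: the prior is a point mass, whose MLE is the mean variance
        # (for exactly-constant s2 this makes shrinkage a strict no-op)
        return _D0_CLIP[1], float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    d0 = float(np.clip(d0, *_D0_CLIP))
    s0_sq = float(np.exp(e.mean() + float(special.digamma(d0 / 2)) - math.log(d0 / 2)))
    return d0, s0_sq


def moderated_t(
    log2fc: float, s2: float, dg: float, d0: float, s0_sq: float, c: float
) -> tuple[float, float]:
    """Moderated t and two-tailed p for one gene with a known prior.

    s_tilde^2 = (d0 s0^2 + dg s2)/(d0 + dg); t = log2fc/(s_tilde c) on
    d0 + dg df.  In the d0 -> inf limit t -> log2fc/(s0 c) with normal p.
    """
    if math.isinf(d0):
        t = log2fc / (math.sqrt(s0_sq) * c)
        return t, float(2 * stats.norm.sf(abs(t)))
    s_tilde_sq = (d0 * s0_sq + dg * s2) / (d0 + dg)
    t = log2fc / (math.sqrt(s_tilde_sq) * c)
    return t, float(2 * stats.t.sf(abs(t), d0 + dg))


def _design_matrix(design: ExperimentDesign, samples: list[str]) -> tuple[np.ndarray, float]:
    """Design matrix for expression ~ condition + cell_line; returns (X, c).

    Column 0 is the intercept, column 1 the CAF_CM indicator (the contrast);
    c is sqrt((X'X)^-1 [1,1]), the standard-error multiplier of the contrast.
    """
    sub = design.table.loc[samples]
    caf = (sub["condition"] == "CAF_CM").to_numpy(dtype=float)
    lines = sorted(sub["cell_line"].unique())
    cols = [np.ones(len(samples)), caf]
    for line in lines[1:]:
        cols.append((sub["cell_line"] == line).to_numpy(dtype=float))
    X = np.column_stack(cols)
    xtx_inv = np.linalg.pinv(X.T @ X)
    c = float(np.sqrt(xtx_inv[1, 1]))
    return X, c


def fit_linear_contrast(
    matrix: ExpressionMatrix,
    design: ExperimentDesign,
    subtype: str,
    blocked: bool = True,
) -> ContrastResult:
    """Fit the CAF-vs-NAF contrast for every gene of one subtype.

    ``blocked=False`` drops the cell-line blocking term (pooled replicates),
    kept for comparison with the default blocked analysis.
    """
    caf = design.samples(subtype=subtype, condition="CAF_CM")
    naf = design.samples(subtype=subtype, condition="NAF_CM")
    if len(caf) < 2 or len(naf) < 2:
        raise ValueError(
            f"subtype {subtype!r}: need >=2 CAF_CM and >=2 NAF_CM samples "
            f"(have {len(caf)}/{len(naf)})"
        )
    samples = caf + naf
    if blocked:
        X, c = _design_matrix(design, samples)
    else:
        X = np.column_stack(
            [np.ones(len(samples)),
             (design.table.loc[samples, "condition"] == "CAF_CM").to_numpy(float)]
        )
        c = float(np.sqrt(np.linalg.pinv(X.T @ X)[1, 1]))
    rank = np.linalg.matrix_rank(X)
    dg = len(samples) - rank
    if dg < 2:
        raise ValueError(f"only {dg} residual degrees of freedom; need >= 2")

    Y = matrix.values[samples].to_numpy(dtype=float)  # genes x samples
    beta = Y @ np.linalg.pinv(X).T  # genes x params
    resid = Y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / dg
    n_floored = int((s2 < _VAR_FLOOR).sum())
    if n_floored:
        logger.warning("%d zero-variance genes; variance floored at %g",
                       n_floored, _VAR_FLOOR)
        s2 = np.maximum(s2, _VAR_FLOOR)

    d0, s0_sq = estimate_variance_prior(s2, dg)
    if d0 >= _D0_INFINITE:
        logger.info("prior df effectively infinite (d0 = %g)", d0)
        s_tilde_sq = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s_tilde_sq = (d0 * s0_sq + dg * s2) / (d0 + dg)
        df_total = d0 + dg
    log2fc = beta[:, 1]
    t_mod = log2fc / (np.sqrt(s_tilde_sq) * c)
    p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "avg_expr": Y.mean(axis=1),
            "s2": s2,
            "df_residual": float(dg),
            "t_mod": t_mod,
            "p": p,
        },
        index=matrix.values.index,
    )
    return ContrastResult(table, d0=d0, s0_sq=s0_sq, subtype=subtype)


def call_de(contrast: ContrastResult, th: DEThresholds | None = None) -> set[tuple[str, str]]:
    """Apply the dual threshold; returns {(gene_id, "up"/"down")}.

    A gene is DE iff p < p_cut and its natural-scale fold change is strictly
    outside [fc_low, fc_high]; both inequalities strict, so FC exactly at a
    gate is not called.
    """
    th = th or DEThresholds()
    fc = np.exp2(contrast.table["log2fc"])
    p = contrast.table["p"]
    de_mask = (p < th.p_cut) & ((fc > th.fc_high) | (fc < th.fc_low))
    out = set()
    for gene in contrast.table.index[de_mask]:
        direction = "up" if fc[gene] > th.fc_high else "down"
        out.add((gene, direction))
    return out
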