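"""Seeded generators for the cell-line treatment experiment and clinical cohorts.

Two generators emulate the data the pipeline was designed for:

* :func:`simulate_cellline_experiment` — nine breast cancer cell lines (three
  per subtype: luminal, HER2+, basal-like) profiled after 72 h exposure to
  conditioned medium from cancer-associated fibroblasts (CAF_CM), normal
  fibroblasts (NAF_CM) or serum-free control (CTRL), in biological
  triplicate.  Differentially expressed genes are planted per subtype in the
  CAF-vs-NAF contrast, gene-wise variances are drawn from a scaled-inverse-
  chi-square prior so the empirical-Bayes moderated-t model is well
  specified, and Illumina-style detection p-values are emitted.

* :func:`simulate_cohort` — a clinical breast-cancer cohort with bimodal
  ESR1/ERBB2 reporter expression defining subtype, a latent microenvironment
  activation state imprinted on signature genes, and distant-metastasis-free
  survival times drawn from an exponential baseline scaled by planted
  log-hazard coefficients (microenvironment status, age > 50, size > 2 cm,
  GGI > 0, and a GGI-by-time interaction with g(t) = log t).

Both generators return the ground truth (:class:`SimTruth`) against which
recovery is tested, and are bit-deterministic given their config and seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .core_io import (
    SUBTYPES,
    CONDITIONS,
    CohortAnnotation,
    ExperimentDesign,
    ExpressionMatrix,
)
from .signature import MuEnvSignature

__all__ = [
    "SimTruth",
    "CellLineSimConfig",
    "CohortSimConfig",
    "simulate_cellline_experiment",
    "simulate_cohort",
    "calibrate_baseline_hazard",
    "TABLE1_HAZARD_COEFS",
    "ACTIVATED_FRACTIONS",
    "DE_COUNTS",
]

#: Planted per-subtype differential-expression gene counts for the CAF-vs-NAF
#: contrast (luminal / HER2+ / basal-like).
DE_COUNTS = {"luminal": 69, "her2": 114, "basal": 10}

#: Latent microenvironment-activated fraction per clinical subtype.
ACTIVATED_FRACTIONS = {"luminal": 0.43, "her2": 0.64, "basal": 0.79}

#: Default planted log-hazard coefficients (multivariable model):
#: hazard ratios 2.098 (muenv), 1.334 (age > 50), 2.093 (size > 2 cm),
#: 6.214 (GGI > 0) and 0.112 for the GGI-by-time interaction on g(t) = log t.
TABLE1_HAZARD_COEFS = {
    "muenv": math.log(2.098),
    "age_hi": math.log(1.334),
    "size_hi": math.log(2.093),
    "ggi_hi": math.log(6.214),
    "ggi_by_time": math.log(0.112),
}

#: Hazard only accrues log-time dependence beyond this age (months); with a
#: strongly negative interaction coefficient a pure log-t hazard diverges at 0.
_TT_FLOOR = 1.0


@dataclass
class SimTruth:
    """Ground truth emitted by the generators.

    planted_de        gene_id -> (subtype, true_log2fc)
    latent_state      sample_id -> "activated" | "quiescent"
    hazard_coefs      covariate -> true log-hazard coefficient
    subtype_truth     sample_id -> subtype
    seed              the seed the generator consumed
    """

    planted_de: dict[str, tuple[str, float]] = field(default_factory=dict)
    latent_state: dict[str, str] = field(default_factory=dict)
    hazard_coefs: dict[str, float] = field(default_factory=dict)
    subtype_truth: dict[str, str] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "planted_de": {g: list(v) for g, v in self.planted_de.items()},
                    "latent_state": self.latent_state,
                    "hazard_coefs": self.hazard_coefs,
                    "subtype_truth": self.subtype_truth,
                    "seed": self.seed,
                },
                fh,
                indent=1,
                sort_keys=True,
            )


# ---------------------------------------------------------------------------
# Cell-line experiment
# ---------------------------------------------------------------------------


@dataclass
class CellLineSimConfig:
    """Configuration of the cell-line conditioned-medium experiment.

    Defaults reproduce the study design: 22,000 genes (so the chance
    expectation at p = 1e-4 is 2.2 genes), 3 cell lines per subtype, 3
    conditions, biological triplicates, planted DE counts 69/114/10 with 80%
    upregulated, and a planted effect of |log2 FC| = 1.5.  Gene variances
    follow a scaled-inverse-chi-square(d0, s0^2) prior.
    """

    n_genes: int = 22_000
    lines_per_subtype: int = 3
    replicates: int = 3
    de_counts: dict[str, int] = field(default_factory=lambda: dict(DE_COUNTS))
    frac_up: float = 0.8
    de_log2fc: float = 1.5
    de_log2fc_spread: float = 1.0
    d0: float = 4.0
    s0_sq: float = 0.0625
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    line_effect_sd: float = 0.25
    noise_scale: float = 1.0
    expressed_fraction: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValueError("need at least 2 replicates")
        if sum(self.de_counts.values()) > self.n_genes:
            raise ValueError("more planted DE genes than genes")
        for s in self.de_counts:
            if s not in SUBTYPES:
                raise ValueError(f"unknown subtype {s!r} in de_counts")


_CELL_LINES = {
    "luminal": ["T47D", "MCF7", "ZR75.1"],
    "her2": ["SkBr3", "BT474", "MDA-MB-361"],
    "basal": ["MDA-MB-468", "BT20", "MDA-MB-231"],
}


def _line_names(cfg: CellLineSimConfig) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for s in SUBTYPES:
        canonical = _CELL_LINES[s]
        if cfg.lines_per_subtype <= len(canonical):
            out[s] = canonical[: cfg.lines_per_subtype]
        else:
            out[s] = canonical + [
                f"{s}_line{i}" for i in range(len(canonical), cfg.lines_per_subtype)
            ]
    return out


def simulate_cellline_experiment(
    cfg: CellLineSimConfig,
) -> tuple[ExpressionMatrix, ExperimentDesign, SimTruth]:
    """Simulate the conditioned-medium experiment with planted DE genes."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lines = _line_names(cfg)

    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    rows = []
    for s in SUBTYPES:
        for line in lines[s]:
            for cond in CONDITIONS:
                for rep in range(1, cfg.replicates + 1):
                    rows.append((f"{line}.{cond}.r{rep}", line, s, cond, rep))
    design = ExperimentDesign(
        pd.DataFrame(
            [r[1:] for r in rows],
            index=[r[0] for r in rows],
            columns=["cell_line", "subtype", "condition", "replicate"],
        )
    )
    n_samples = len(rows)
    subtype_of = design.table["subtype"].to_numpy()
    cond_of = design.table["condition"].to_numpy()
    line_of = design.table["cell_line"].to_numpy()
    all_lines = sorted(set(line_of))
    line_idx = np.array([all_lines.index(l) for l in line_of])

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    # scaled inverse chi-square: s2_g = d0 * s0^2 / chi2_{d0}
    gene_var = cfg.d0 * cfg.s0_sq / rng.chisquare(cfg.d0, size=cfg.n_genes)
    gene_sd = cfg.noise_scale * np.sqrt(gene_var)
    line_effects = rng.normal(0.0, cfg.line_effect_sd, size=(cfg.n_genes, len(all_lines)))

    # choose planted DE genes: disjoint blocks per subtype; planted magnitudes
    # vary around de_log2fc (real treatment effects are not all equal)
    perm = rng.permutation(cfg.n_genes)
    planted: dict[str, tuple[str, float]] = {}
    offset = 0
    de_shift = np.zeros((cfg.n_genes, n_samples))
    half_spread = min(cfg.de_log2fc_spread / 2, cfg.de_log2fc - np.log2(1.5))
    for s in SUBTYPES:
        k = cfg.de_counts.get(s, 0)
        idx = perm[offset : offset + k]
        offset += k
        n_up = int(round(cfg.frac_up * k))
        signs = np.array([1.0] * n_up + [-1.0] * (k - n_up))
        mags = rng.uniform(cfg.de_log2fc - half_spread,
                           cfg.de_log2fc + half_spread, size=k)
        caf_cols = (subtype_of == s) & (cond_of == "CAF_CM")
        for g, sign, mag in zip(idx, signs, mags):
            lfc = sign * mag
            planted[gene_ids[g]] = (s, float(lfc))
            de_shift[g, caf_cols] = lfc

    noise = rng.normal(0.0, 1.0, size=(cfg.n_genes, n_samples)) * gene_sd[:, None]
    values = baseline[:, None] + line_effects[:, line_idx] + de_shift + noise

    # detection p-values: expressed genes are detected (p < 0.01) in every
    # sample; unexpressed genes never are.  Planted DE genes always expressed.
    expressed = rng.random(cfg.n_genes) < cfg.expressed_fraction
    for gid in planted:
        expressed[gene_ids.index(gid)] = True
    detection = np.empty((cfg.n_genes, n_samples))
    detection[expressed] = rng.uniform(0.0, 0.005, size=(int(expressed.sum()), n_samples))
    detection[~expressed] = rng.uniform(0.02, 1.0, size=(int((~expressed).sum()), n_samples))

    sample_ids = [r[0] for r in rows]
    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.DataFrame(detection, index=gene_ids, columns=sample_ids),
        platform_tag="synthetic-beadarray",
    )
    truth = SimTruth(planted_de=planted, seed=cfg.seed)
    return matrix, design, truth


# ---------------------------------------------------------------------------
# Clinical cohort
# ---------------------------------------------------------------------------


@dataclass
class CohortSimConfig:
    """Configuration of the synthetic clinical cohort.

    Survival model: exponential baseline hazard ``baseline_hazard`` (per
    month) scaled by exp(sum beta_j x_j + beta_gt * x_ggi * log max(t, 1)).
    Binary covariates age > 50, size > 2 cm and GGI > 0 each have prevalence
    ~0.5 (via continuous age/size/GGI draws); the microenvironment covariate
    is the latent activation state with subtype-specific prevalence.
    Censoring is independent exponential plus administrative at ``horizon``
    months.  If ``target_events`` is set the baseline hazard is calibrated so
    the expected observed event count matches it.
    """

    n_patients: int = 500
    subtype_fracs: dict[str, float] = field(
        default_factory=lambda: {"luminal": 0.55, "her2": 0.20, "basal": 0.25}
    )
    activated_frac: dict[str, float] = field(
        default_factory=lambda: dict(ACTIVATED_FRACTIONS)
    )
    effect_size: float = 1.5
    noise_sd: float = 0.5
    marker_low_mean: float = 6.0
    marker_high_mean: float = 11.0
    marker_sd: float = 0.8
    her2_esr1_pos_frac: float = 0.5
    n_filler_genes: int = 200
    hazard_coefs: dict[str, float] = field(
        default_factory=lambda: dict(TABLE1_HAZARD_COEFS)
    )
    muenv_attenuation: float = 1.0
    treatment: str = "none"
    baseline_hazard: Optional[float] = 0.002
    target_events: Optional[int] = None
    censoring_rate: float = 0.003
    horizon: float = 120.0
    max_redraws: int = 10
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.subtype_fracs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("subtype fractions must sum to 1")
        for d in (self.subtype_fracs, self.activated_frac):
            for s, f in d.items():
                if not 0.0 <= f <= 1.0:
                    raise ValueError(f"fraction for {s!r} outside [0,1]")
        if self.baseline_hazard is None and self.target_events is None:
            raise ValueError("set either baseline_hazard or target_events")
        if self.treatment not in ("none", "tam", "chemo"):
            raise ValueError(f"unknown treatment {self.treatment!r}")


def _effective_coefs(cfg: CohortSimConfig) -> dict[str, float]:
    coefs = dict(cfg.hazard_coefs)
    if "muenv" in coefs:
        coefs["muenv"] *= cfg.muenv_attenuation
    return coefs


def _cum_hazard(t: np.ndarray, lam: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Integrated hazard of lam * max(t,1)^a (a = beta_gt * x_ggi)."""
    t = np.asarray(t, dtype=float)
    out = np.where(t <= _TT_FLOOR, lam * t, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        tail = np.where(
            np.isclose(a, -1.0),
            np.log(np.maximum(t, _TT_FLOOR)),
            (np.maximum(t, _TT_FLOOR) ** (1.0 + a) - 1.0) / (1.0 + a),
        )
    return np.where(t <= _TT_FLOOR, lam * t, lam * (_TT_FLOOR + tail))


def _invert_cum_hazard(e: np.ndarray, lam: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Solve Lambda(t) = e for t; returns inf where e exceeds Lambda(inf)."""
    e = np.asarray(e, dtype=float)
    t = np.where(e <= lam * _TT_FLOOR, e / lam, np.nan)
    u = e / lam - _TT_FLOOR  # residual integral beyond the floor
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        base = 1.0 + (1.0 + a) * u
        t_tail = np.where(
            np.isclose(a, -1.0),
            np.exp(u),
            np.where(base > 0, base ** (1.0 / (1.0 + a)), np.inf),
        )
        # for a < -1, base <= 0 means the total hazard is exhausted: no event
        t_tail = np.where((a < -1.0) & (base <= 0), np.inf, t_tail)
    return np.where(np.isnan(t), t_tail, t)


def _expected_events(
    lam0: float,
    eta: np.ndarray,
    a: np.ndarray,
    censoring_rate: float,
    horizon: float,
    weights: Optional[np.ndarray] = None,
    n_grid: int = 512,
) -> float:
    """E[# observed events] by numerical quadrature over [0, horizon]."""
    t = np.linspace(1e-6, horizon, n_grid)
    lam = lam0 * np.exp(eta)[:, None]
    a2 = a[:, None]
    tt = np.maximum(t[None, :], _TT_FLOOR) ** a2
    hazard = lam * tt
    cumhaz = _cum_hazard(t[None, :], lam, a2)
    dens = hazard * np.exp(-cumhaz) * np.exp(-censoring_rate * t[None, :])
    per_subject = np.trapezoid(dens, t, axis=1)
    if weights is None:
        return float(per_subject.sum())
    return float((per_subject * weights).sum())


def _calibrate_baseline(
    cfg: CohortSimConfig,
    eta: np.ndarray,
    a: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    lo, hi = 1e-8, 1.0
    target = float(cfg.target_events)
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if _expected_events(mid, eta, a, cfg.censoring_rate, cfg.horizon,
                            weights) < target:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def calibrate_baseline_hazard(cfg: CohortSimConfig) -> float:
    """Baseline hazard (per month) giving E[# observed events] = target_events.

    The expectation is taken over the exact covariate distribution of the
    generator (marginal activated fraction across subtypes; prevalence 0.5
    for each dichotomized clinical covariate) by enumerating the 16 binary
    covariate patterns, so the calibration does not depend on any particular
    covariate draw.  The returned rate can be fed back as ``baseline_hazard``
    (with ``target_events=None``) to amortize the calibration over seeds.
    """
    if cfg.target_events is None:
        raise ValueError("target_events not set")
    coefs = _effective_coefs(cfg)
    p_act = sum(
        cfg.subtype_fracs[s] * cfg.activated_frac.get(s, 0.0)
        for s in cfg.subtype_fracs
    )
    marginals = {"muenv": p_act, "age_hi": 0.5, "size_hi": 0.5, "ggi_hi": 0.5}
    names = list(marginals)
    etas, aas, weights = [], [], []
    for bits in range(16):
        pattern = {nm: (bits >> i) & 1 for i, nm in enumerate(names)}
        w = 1.0
        for nm in names:
            p = marginals[nm]
            w *= p if pattern[nm] else 1.0 - p
        eta = sum(
            beta * pattern[nm]
            for nm, beta in coefs.items()
            if nm != "ggi_by_time"
        )
        etas.append(eta)
        aas.append(coefs.get("ggi_by_time", 0.0) * pattern["ggi_hi"])
        weights.append(w)
    eta = np.asarray(etas)
    a = np.asarray(aas)
    w = cfg.n_patients * np.asarray(weights)
    return _calibrate_baseline(cfg, eta, a, w)


def simulate_cohort(
    cfg: CohortSimConfig,
    signatures: Optional[dict[str, "MuEnvSignature"]] = None,
) -> tuple[ExpressionMatrix, CohortAnnotation, SimTruth]:
    """Simulate a clinical cohort with latent microenvironment activation.

    ``signatures`` maps subtype -> signature to imprint: activated samples
    have each signature gene of their own subtype's signature shifted along
    its DE direction by ``cfg.effect_size`` log2 units.  With ``signatures``
    None only the ESR1/ERBB2 reporter rows and filler genes are emitted
    (sufficient for survival-parameter studies).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    sample_ids = [f"P{i:04d}" for i in range(n)]

    # subtype truth and latent activation
    subtype_names = list(cfg.subtype_fracs)
    probs = np.array([cfg.subtype_fracs[s] for s in subtype_names])
    subtype = rng.choice(subtype_names, size=n, p=probs)
    act_p = np.array([cfg.activated_frac.get(s, 0.0) for s in subtype])
    activated = rng.random(n) < act_p

    # clinical covariates (continuous, dichotomized downstream)
    age = rng.uniform(35.0, 65.0, size=n)
    size = rng.uniform(0.5, 3.5, size=n)
    ggi = rng.normal(0.0, 1.0, size=n)

    coefs = _effective_coefs(cfg)
    x = {
        "muenv": activated.astype(float),
        "age_hi": (age > 50).astype(float),
        "size_hi": (size > 2).astype(float),
        "ggi_hi": (ggi > 0).astype(float),
    }
    eta = np.zeros(n)
    for name, beta in coefs.items():
        if name == "ggi_by_time":
            continue
        if name not in x:
            raise ValueError(f"unknown hazard covariate {name!r}")
        eta += beta * x[name]
    a = coefs.get("ggi_by_time", 0.0) * x["ggi_hi"]

    # target_events, when set, takes precedence over a fixed baseline hazard
    if cfg.target_events is not None:
        lam0 = _calibrate_baseline(cfg, eta, a)
    else:
        lam0 = cfg.baseline_hazard

    lam = lam0 * np.exp(eta)
    for attempt in range(cfg.max_redraws + 1):
        e = rng.exponential(1.0, size=n)
        t_event = _invert_cum_hazard(e, lam, a)
        c = np.minimum(rng.exponential(1.0 / cfg.censoring_rate, size=n), cfg.horizon)
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
        time = np.maximum(time, 1e-3)  # keep times strictly positive
        if event.sum() >= 1:
            break
    else:
        raise RuntimeError("all-censored cohort after redraw cap; raise baseline hazard")

    # expression: reporters + signature genes + filler
    gene_rows: dict[str, np.ndarray] = {}
    low, high, msd = cfg.marker_low_mean, cfg.marker_high_mean, cfg.marker_sd
    esr1_hi = np.where(
        subtype == "luminal",
        True,
        np.where(subtype == "basal", False, rng.random(n) < cfg.her2_esr1_pos_frac),
    ).astype(bool)
    erbb2_hi = subtype == "her2"
    gene_rows["ESR1"] = rng.normal(np.where(esr1_hi, high, low), msd)
    gene_rows["ERBB2"] = rng.normal(np.where(erbb2_hi, high, low), msd)

    if signatures is not None:
        # activated tumors recapitulate their subtype's CAF-treated reference
        # profile: each signature gene is shifted along its own centroid
        # pattern, normalized so the mean absolute shift is effect_size
        sig_genes: dict[str, tuple[str, float]] = {}
        for s, sig in signatures.items():
            scale = np.mean([abs(v) for v in sig.centroid.values()])
            for gene_id, direction in sig.genes:
                rel = (
                    sig.centroid[gene_id] / scale
                    if scale > 0
                    else (1.0 if direction == "up" else -1.0)
                )
                sig_genes[gene_id] = (s, rel)
        for gene_id, (s, rel) in sig_genes.items():
            base = rng.normal(7.0, 1.0)
            shift = np.where(
                activated & (subtype == s), rel * cfg.effect_size, 0.0
            )
            gene_rows[gene_id] = base + shift + rng.normal(0.0, cfg.noise_sd, size=n)

    for i in range(cfg.n_filler_genes):
        gene_rows[f"F{i:04d}"] = rng.normal(rng.normal(7.0, 1.0), cfg.noise_sd, size=n)

    values = pd.DataFrame(gene_rows, index=sample_ids).T
    matrix = ExpressionMatrix(values, platform_tag="synthetic-cohort")

    ann = CohortAnnotation(
        pd.DataFrame(
            {
                "time_months": time,
                "event": event,
                "age_years": age,
                "size_cm": size,
                "ggi": ggi,
                "treatment": cfg.treatment,
            },
            index=sample_ids,
        )
    )
    truth = SimTruth(
        latent_state={
            sid: ("activated" if act else "quiescent")
            for sid, act in zip(sample_ids, activated)
        },
        hazard_coefs=dict(coefs),
        subtype_truth=dict(zip(sample_ids, subtype)),
        seed=cfg.seed,
    )
    return matrix, ann, truth
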