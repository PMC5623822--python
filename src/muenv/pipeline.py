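"""End-to-end orchestration: simulate -> preprocess -> DE -> GSEA -> signature
-> subtype -> score -> survival, writing per-stage artifacts and a manifest.

Each stage writes the documented TSV/JSON files into the output directory so
stages can also be run independently through the CLI.  A run is fully
reproducible from its manifest (config hash + seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_io import (
    SUBTYPES,
    SUBTYPE_LABELS,
    ExpressionMatrix,
    GeneSetCollection,
    filter_probes,
    quantile_normalize,
    write_cohort_annotation,
    write_expression_tsv,
    write_gmt,
)
from .diffexpr import ContrastResult, DEThresholds, call_de, fit_linear_contrast
from .enrichment import gsea_preranked
from .signature import (
    MuEnvSignature,
    SubtypeThresholds,
    assign_subtype,
    bimodal_threshold,
    build_signature,
    classify_muenv,
    mean_center,
)
from .survival import (
    administrative_censor,
    cox_fit,
    dichotomize_covariates,
    km_estimate,
    logrank_test,
    schoenfeld_test,
    univariable_cox,
)
from .synthetic import (
    CellLineSimConfig,
    CohortSimConfig,
    simulate_cellline_experiment,
    simulate_cohort,
)

logger = logging.getLogger("muenv")


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic end-to-end run."""

    cellline: CellLineSimConfig = field(default_factory=CellLineSimConfig)
    cohort: CohortSimConfig = field(default_factory=CohortSimConfig)
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    n_perm: int = 1000
    gsea_weight: float = 1.0
    n_random_sets: int = 50
    min_overlap: int = 10
    subtype_cut_mode: str = "auto"  # "auto" (bimodal mixture) or "manual"
    manual_cuts: tuple[float, float] = (0.0, 0.0)
    ten_year: bool = True
    multivariable: bool = True
    run_gsea: bool = True
    out_dir: str = "muenv_run"
    seed: int = 0
    log_level: str = "INFO"

    def hash(self) -> str:
        """Hash of the scientific configuration (paths and log level excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        d.pop("log_level", None)
        enc = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(enc.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if key == "cellline":
                cfg.cellline = CellLineSimConfig(**val)
            elif key == "cohort":
                cfg.cohort = CohortSimConfig(**val)
            elif key == "thresholds":
                cfg.thresholds = DEThresholds(**val)
            elif hasattr(cfg, key):
                setattr(cfg, key, val)
            else:
                raise ValueError(f"unknown config key {key!r}")
        return cfg


def _setup_logging(out_dir: Path, level: str) -> None:
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr),
                    logging.FileHandler(out_dir / "run.log", mode="w")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def make_gene_set_collection(
    contrasts: dict[str, ContrastResult],
    de_sets: dict[str, set],
    n_random: int,
    seed: int,
) -> GeneSetCollection:
    """Assemble a GSEA collection: one planted set per subtype DE list plus
    random background sets drawn from the tested gene universe."""
    rng = np.random.default_rng(seed)
    any_contrast = next(iter(contrasts.values()))
    universe = list(any_contrast.table.index)
    sets: dict[str, set[str]] = {}
    for s, de in de_sets.items():
        if de:
            sets[f"PLANTED_{s.upper()}"] = {g for g, _ in de}
    for i in range(n_random):
        k = int(rng.integers(15, 101))
        members = rng.choice(len(universe), size=k, replace=False)
        sets[f"RANDOM_{i:03d}"] = {universe[j] for j in members}
    return GeneSetCollection(sets, source="synthetic")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full synthetic analysis; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out, cfg.log_level)
    t0 = _time.time()
    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.hash(),
        "seed": cfg.seed,
        "stages": {},
        "warnings": [],
    }
    stage_t = _time.time()

    def _done(stage: str) -> None:
        nonlocal stage_t
        dt = _time.time() - stage_t
        manifest["stages"][stage] = round(dt, 3)
        logger.info("stage %s done in %.2fs", stage, dt)
        stage_t = _time.time()

    try:
        # 1. cell-line experiment
        cl_cfg = dataclasses.replace(cfg.cellline, seed=cfg.seed)
        cl_matrix, design, cl_truth = simulate_cellline_experiment(cl_cfg)
        design.table.to_csv(out / "cellline_design.tsv", sep="\t",
                            index_label="sample_id")
        cl_truth.to_json(str(out / "cellline_truth.json"))
        _done("simulate_celllines")

        # 2. preprocess: detection filter then quantile normalization
        cl_matrix = filter_probes(cl_matrix)
        cl_matrix = quantile_normalize(cl_matrix)
        write_expression_tsv(cl_matrix, str(out / "cellline_expression.tsv"))
        _done("preprocess")

        # 3. DE per subtype
        contrasts: dict[str, ContrastResult] = {}
        de_sets: dict[str, set] = {}
        for s in SUBTYPES:
            contrast = fit_linear_contrast(cl_matrix, design, s)
            contrasts[s] = contrast
            de_sets[s] = call_de(contrast, cfg.thresholds)
            contrast.to_tsv(str(out / f"contrast_{s}.tsv"), cfg.thresholds)
            pd.DataFrame(sorted(de_sets[s]), columns=["gene_id", "direction"]).to_csv(
                out / f"de_{s}.tsv", sep="\t", index=False
            )
            logger.info("subtype %s: %d DE genes", s, len(de_sets[s]))
        _done("de")

        # 4. GSEA on the ranked list of each subtype
        if cfg.run_gsea:
            collection = make_gene_set_collection(
                contrasts, de_sets, cfg.n_random_sets, cfg.seed + 1
            )
            write_gmt(collection, str(out / "gene_sets.gmt"))
            for s in SUBTYPES:
                res = gsea_preranked(
                    contrasts[s].ranked_genes(), collection,
                    n_perm=cfg.n_perm, weight=cfg.gsea_weight, seed=cfg.seed + 2,
                )
                res.to_tsv(str(out / f"gsea_{s}.tsv"))
            _done("gsea")

        # 5. signatures from the centered cell-line collection
        centered_cl = mean_center(cl_matrix)
        signatures: dict[str, MuEnvSignature] = {}
        for s in SUBTYPES:
            if not de_sets[s]:
                manifest["warnings"].append(f"no DE genes for {s}; no signature")
                continue
            sig = build_signature(
                de_sets[s], centered_cl, design, s,
                provenance={"config_hash": cfg.hash(), "thresholds":
                            dataclasses.asdict(cfg.thresholds)},
            )
            signatures[s] = sig
            sig.to_tsv(str(out / f"signature_{s}.tsv"))
        _done("signature")

        # 6. cohort simulation (imprinting the signatures)
        co_cfg = dataclasses.replace(cfg.cohort, seed=cfg.seed + 3)
        co_matrix, annotation, co_truth = simulate_cohort(co_cfg, signatures)
        co_truth.to_json(str(out / "cohort_truth.json"))
        write_expression_tsv(co_matrix, str(out / "cohort_expression.tsv"))
        _done("simulate_cohort")

        # 7. subtype assignment from reporter bimodality
        if cfg.subtype_cut_mode == "auto":
            esr1_fit = bimodal_threshold(
                co_matrix.values.loc["ESR1"].to_numpy(), seed=cfg.seed + 4
            )
            erbb2_fit = bimodal_threshold(
                co_matrix.values.loc["ERBB2"].to_numpy(), seed=cfg.seed + 5
            )
            cuts = SubtypeThresholds(
                esr1_cut=esr1_fit.threshold, erbb2_cut=erbb2_fit.threshold
            )
        else:
            cuts = SubtypeThresholds(
                esr1_cut=cfg.manual_cuts[0], erbb2_cut=cfg.manual_cuts[1]
            )
        subtype = assign_subtype(co_matrix, cuts)
        annotation.table["subtype"] = subtype
        write_cohort_annotation(annotation, str(out / "cohort_annotation.tsv"))
        _done("subtype")

        # 8. score and dichotomize within each subtype
        centered_cohort = mean_center(co_matrix)
        calls = {}
        for s, sig in signatures.items():
            members = subtype.index[subtype == s]
            if len(members) == 0:
                continue
            try:
                call = classify_muenv(
                    centered_cohort.subset_samples(list(members)), sig,
                    min_overlap=cfg.min_overlap,
                )
            except ValueError as exc:
                # a single subtype falling under the overlap floor should not
                # abort the other subtypes' analyses
                manifest["warnings"].append(f"scoring skipped for {s}: {exc}")
                logger.warning("scoring skipped for %s: %s", s, exc)
                continue
            call.to_tsv(str(out / f"muenv_calls_{s}.tsv"))
            calls[s] = call
            logger.info(
                "subtype %s (%s): %.1f%% muENV-positive of %d",
                s, SUBTYPE_LABELS[s], 100 * call.positive_rate(), len(members),
            )
        _done("score")

        # 9. survival per subtype
        surv_summary = {}
        for s, call in calls.items():
            ids = call.table.index
            sub_ann = annotation.table.loc[ids]
            time_v = sub_ann["time_months"].to_numpy(dtype=float)
            event_v = sub_ann["event"].to_numpy(dtype=int)
            if cfg.ten_year:
                time_v, event_v = administrative_censor(time_v, event_v)
            muenv = (call.table["status"] == "positive").astype(int).to_numpy()
            if event_v.sum() == 0 or len(set(muenv)) < 2:
                manifest["warnings"].append(f"survival skipped for {s}")
                continue
            for grp, km in km_estimate(time_v, event_v, muenv).items():
                km.to_frame().to_csv(
                    out / f"km_{s}_muenv{grp}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
            chi2, logrank_p = logrank_test(time_v, event_v, muenv)
            uni = univariable_cox(muenv, time_v, event_v, name="muenv")
            schoenfeld_test(uni, time_v, event_v)
            uni.to_tsv(str(out / f"cox_uni_{s}.tsv"))
            entry = {
                "logrank_chi2": chi2,
                "logrank_p": logrank_p,
                "uni_hr": uni.hr("muenv"),
                "n": int(uni.n),
                "n_events": int(uni.n_events),
            }
            if cfg.multivariable and {"age_years", "size_cm", "ggi"} <= set(
                sub_ann.columns
            ):
                from .core_io import CohortAnnotation

                cov = dichotomize_covariates(CohortAnnotation(sub_ann))
                cov.insert(0, "muenv", muenv)
                try:
                    multi = cox_fit(cov, time_v, event_v,
                                    tt_spec=("ggi_hi", None))
                except ValueError as exc:
                    # few-event subtypes can separate; keep the other outputs
                    manifest["warnings"].append(
                        f"multivariable fit skipped for {s}: {exc}")
                    logger.warning("multivariable fit skipped for %s: %s", s, exc)
                else:
                    multi.to_tsv(str(out / f"cox_multi_{s}.tsv"))
                    entry["multi_hr"] = multi.hr("muenv")
            surv_summary[s] = entry
        manifest["survival"] = surv_summary
        _done("survive")

        manifest["elapsed"] = round(_time.time() - t0, 3)
        manifest["status"] = "OK"
    except Exception as exc:
        manifest["status"] = "FAILED"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        with open(out / "FAILED", "w") as fh:
            fh.write(manifest["error"] + "\n")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
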