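"""End-to-end pipeline orchestration.

Executes the stages in fixed order — simulate (or load) → per-fluid QC →
migration scores → variance partitioning → metagenome preparation →
cross-sectional associations → paired pre/post contrasts — and writes a
manifest recording the configuration hash, the seed, per-stage counts
and a SHA-256 digest of every output file. Re-running with the same
configuration and inputs reproduces identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sfio
from .association import fit_feature_model, fit_paired_model, transform_abundance
from .containers import FeatureTable
from .fluidstats import bray_curtis_matrix, pareto_pca, permanova
from .prep import dedup_correlated, encode_covariates, prefilter
from .qc import run_qc_chain
from .scores import compute_migration_scores, regress_score_on_clinical
from .simulate import SimulationParams, generate_cohort, generate_injection_sequence

log = logging.getLogger("salivaflux")

FLUIDS = ("plasma", "glandular", "whole")


@dataclass
class PipelineConfig:
    """All pipeline settings with the study's default thresholds."""

    outdir: str = "salivaflux_out"
    seed: int = 0
    simulate: dict | None = None          # SimulationParams overrides, or None
    inputs: dict | None = None            # fluid/feature/cohort table paths
    cv_max_pct: float = 30.0
    blank_ratio_min: float = 3.0
    lowess_span: float = 0.5
    qc_interval: int = 6
    drift_slope: float = 0.002            # linear instrument drift per injection
    prevalence_min: float = 0.1
    abundance_min: float | None = None    # None → level-specific default
    rho_min: float = 0.9
    flow_cutoff: float = 0.67
    fdr_target: float = 0.25
    n_perm: int = 999
    n_bins: int = 7
    exposures: tuple = ("group", "GlcFruMig", "hba1c")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0 < self.cv_max_pct:
            raise ValueError("cv_max_pct must be positive")
        if not 0 <= self.prevalence_min <= 1:
            raise ValueError("prevalence_min must be in [0, 1]")
        if not 0 < self.rho_min <= 1:
            raise ValueError("rho_min must be in (0, 1]")
        if not 0 < self.fdr_target <= 1:
            raise ValueError("fdr_target must be in (0, 1]")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.simulate is None and self.inputs is None:
            raise ValueError("either 'simulate' parameters or 'inputs' paths are required")
        if self.inputs is not None:
            # table entries are "<dir>/<stem>" prefixes; cohort is a real file
            missing = []
            for key, p in self.inputs.items():
                probe = Path(p) if key == "cohort" else Path(f"{p}_values.tsv")
                if not probe.exists():
                    missing.append(str(probe))
            if missing:
                raise FileNotFoundError(f"input paths do not exist: {missing}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exposures"] = list(self.exposures)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def migration_association(cohort_obj, exposure: str = "GlcFruMig",
                          adjust=("age_tertile", "pisa_tertile",
                                  "caries_tertile", "flow_group")):
    """In-memory baseline workflow: scores → prefilter → per-feature model.

    Normalizes each fluid's saccharide levels by internal standard and
    collected amount, computes composite migration scores over the
    baseline cross-section, prefilters the species table, encodes the
    clinical covariates and fits the multivariable per-feature model for
    one exposure. Returns ``(scores, association_results)``.
    """
    from .qc import normalize_internal_standard, normalize_sample_amount

    cohort = cohort_obj.cohort
    baseline_ids = list(cohort.index[cohort["timepoint"] == "baseline"])
    tables = {}
    for fluid, tab in cohort_obj.metabolite_tables.items():
        norm = normalize_sample_amount(normalize_internal_standard(tab))
        tables[fluid] = norm.biological[["glucose", "fructose"]]
    scores = compute_migration_scores(tables, ranking_pool=baseline_ids)
    filtered, _ = prefilter(cohort_obj.feature_table)
    encodings = encode_covariates(cohort)
    base_samples = [s for s in filtered.values.columns if s in set(baseline_ids)]
    base_table = FeatureTable(filtered.values[base_samples], filtered.feature_meta)
    if exposure in scores.table.columns:
        exp_series = scores.table.loc[base_samples, exposure]
    else:
        exp_series = cohort.loc[base_samples, exposure]
    results = fit_feature_model(
        base_table, exp_series, covariates=encodings.loc[base_samples],
        adjust=adjust, exposure_name=exposure,
    )
    return scores, results


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "outputs": {},
        "status": "running",
    }
    written: list[Path] = []

    def _record(stage: str, **counts) -> None:
        manifest["stages"][stage] = counts
        log.info("stage %s: %s", stage, counts)

    try:
        # -- stage 1: simulate or load ----------------------------------
        if config.simulate is not None:
            params = SimulationParams(**{**config.simulate, "seed": config.seed})
            cohort_obj = generate_cohort(params)
            drift = (lambda i: 1.0 + config.drift_slope * i) if config.drift_slope else None
            raw_tables = {
                fluid: generate_injection_sequence(
                    tab, qc_interval=config.qc_interval, drift=drift
                )
                for fluid, tab in cohort_obj.metabolite_tables.items()
            }
            features = cohort_obj.feature_table
            cohort = cohort_obj.cohort
            for fluid, tab in raw_tables.items():
                written += sfio.write_metabolite_table(tab, outdir / "simulated", f"{fluid}_raw")
            written += sfio.write_feature_table(features, outdir / "simulated", "species")
            written.append(sfio.write_tsv(cohort, outdir / "simulated" / "cohort.tsv",
                                          index_label="sample_id"))
            truth_path = outdir / "simulated" / "truth.tsv"
            truth_df = pd.DataFrame({
                "M": cohort_obj.truth["M"],
                "cariogenic_load": cohort_obj.truth["cariogenic_load"],
            })
            written.append(sfio.write_tsv(truth_df, truth_path, index_label="sample_id"))
            _record("simulate", n_samples=len(cohort), n_taxa=features.values.shape[0])
        else:
            inputs = config.inputs
            raw_tables = {
                fluid: sfio.read_metabolite_table(Path(inputs[fluid]).parent,
                                                  Path(inputs[fluid]).name)
                for fluid in FLUIDS
            }
            features = sfio.read_feature_table(Path(inputs["features"]).parent,
                                               Path(inputs["features"]).name)
            cohort = pd.read_csv(inputs["cohort"], sep="\t", index_col="sample_id")
            _record("load", n_samples=len(cohort), n_taxa=features.values.shape[0])

        # -- stage 2: per-fluid QC chain --------------------------------
        qc_tables = {}
        for fluid, tab in raw_tables.items():
            filtered, report = run_qc_chain(
                tab, span=config.lowess_span,
                blank_ratio_min=config.blank_ratio_min, cv_max_pct=config.cv_max_pct,
            )
            qc_tables[fluid] = filtered
            written += sfio.write_metabolite_table(filtered, outdir / "qc", f"{fluid}_normalized")
            written.append(sfio.write_json(report.to_dict(),
                                           outdir / "qc" / f"{fluid}_filter_report.json"))
            _record(f"qc_{fluid}", retained=len(report.retained),
                    removed=len(report.removed))

        # -- stage 3: migration scores ----------------------------------
        saccharide_tables = {}
        for fluid, tab in qc_tables.items():
            bio = tab.biological
            for col in ("glucose", "fructose"):
                if col not in bio.columns:
                    raise ValueError(f"{fluid}: saccharide {col!r} lost during QC filtering")
            saccharide_tables[fluid] = bio[["glucose", "fructose"]]
        baseline_ids = list(cohort.index[cohort["timepoint"] == "baseline"])
        scores = compute_migration_scores(
            saccharide_tables, ranking_pool=baseline_ids, n_bins=config.n_bins
        )
        written.append(sfio.write_tsv(scores.table, outdir / "scores" / "migration_scores.tsv"))
        written.append(sfio.write_json(
            {f"{f}|{q}": e for (f, q), e in scores.cutpoints.items()},
            outdir / "scores" / "cutpoints.json",
        ))
        clin_rows = []
        base_cohort = cohort.loc[baseline_ids]
        for clin in ("caries_count", "plaque_index", "pisa", "salivary_flow"):
            if clin in cohort.columns:
                clin_rows.append(regress_score_on_clinical(scores, base_cohort, clin))
        if clin_rows:
            written.append(sfio.write_tsv(pd.DataFrame(clin_rows).set_index("param"),
                                          outdir / "scores" / "clinical_regressions.tsv",
                                          index_label="param"))
        _record("score", n_scored=int(scores.table["GlcFruMig"].notna().sum()),
                n_incomplete=len(scores.incomplete))

        # -- stage 4: variance partitioning -----------------------------
        variance: dict = {}
        rng = np.random.default_rng(config.seed)
        for fluid, tab in qc_tables.items():
            bio = tab.biological
            bio = bio.loc[[s for s in bio.index if s in set(baseline_ids)]]
            groups = cohort.loc[bio.index, "group"].to_numpy()
            dist = bray_curtis_matrix(bio)
            res = permanova(dist.to_numpy(), groups,
                            n_perm=config.n_perm, seed=int(rng.integers(2**31 - 1)),
                            grouping_name="group")
            pca = pareto_pca(bio)
            variance[fluid] = {
                "r_squared": res.r_squared, "pseudo_f": res.pseudo_f,
                "p_value": res.p_value, "n_permutations": res.n_permutations,
                "pc1_var": float(pca.explained_variance_ratio[0]),
                "pc2_var": float(pca.explained_variance_ratio[1]),
            }
        written.append(sfio.write_json(variance, outdir / "variance" / "permanova.json"))
        _record("variance", **{f: round(v["r_squared"], 4) for f, v in variance.items()})

        # -- stage 5: metagenome preparation ----------------------------
        prefiltered, pre_report = prefilter(
            features, prevalence_min=config.prevalence_min, abundance_min=config.abundance_min
        )
        deduped, dedup_report = dedup_correlated(prefiltered, rho_min=config.rho_min)
        encodings = encode_covariates(cohort, flow_cutoff=config.flow_cutoff)
        written += sfio.write_feature_table(deduped, outdir / "prep", "filtered")
        written.append(sfio.write_json(pre_report.to_dict(),
                                       outdir / "prep" / "prefilter_report.json"))
        written.append(sfio.write_json(dedup_report.to_dict(),
                                       outdir / "prep" / "dedup_report.json"))
        written.append(sfio.write_tsv(encodings, outdir / "prep" / "covariates.tsv",
                                      index_label="sample_id"))
        _record("prep", retained=deduped.values.shape[0],
                prefilter_removed=len(pre_report.removed),
                dedup_removed=len(dedup_report.removed_to_representative))

        # -- stage 6: cross-sectional associations ----------------------
        base_samples = [s for s in deduped.values.columns if s in set(baseline_ids)]
        base_table = FeatureTable(deduped.values[base_samples], deduped.feature_meta)
        transformed = transform_abundance(base_table.values)
        exposure_frames = cohort.join(scores.table[["GlcMig", "FruMig", "GlcFruMig"]],
                                      how="left")
        for exposure in config.exposures:
            if exposure not in exposure_frames.columns:
                log.warning("exposure %r not available; skipped", exposure)
                continue
            res = fit_feature_model(
                base_table,
                exposure_frames.loc[base_samples, exposure],
                covariates=encodings.loc[base_samples],
                transformed=transformed,
                exposure_name=exposure,
                fdr_target=config.fdr_target,
            )
            written.append(sfio.write_tsv(res, outdir / "association" / f"{exposure}.tsv",
                                          index_label="feature"))
            _record(f"associate_{exposure}", n_features=len(res),
                    n_significant=int(res["significant"].sum()) if len(res) else 0)

        # -- stage 7: paired pre/post contrasts -------------------------
        post_ids = [s for s in cohort.index if cohort.loc[s, "timepoint"] == "post"]
        if post_ids:
            t2d = cohort[cohort["group"] == "t2d"]
            paired_samples = [s for s in deduped.values.columns if s in set(t2d.index)]
            paired_table = FeatureTable(deduped.values[paired_samples], deduped.feature_meta)
            res = fit_paired_model(
                paired_table,
                timepoint=t2d.loc[paired_samples, "timepoint"],
                participant=t2d.loc[paired_samples, "participant"],
                fdr_target=config.fdr_target,
            )
            written.append(sfio.write_tsv(res, outdir / "association" / "paired_prepost.tsv",
                                          index_label="feature"))
            _record("paired", n_features=len(res),
                    n_significant=int(res["significant"].sum()) if len(res) else 0)

        manifest["status"] = "complete"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(Path(p)) for p in written}
        sfio.write_json(manifest, outdir / "manifest.json")
        raise

    manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(Path(p)) for p in written}
    sfio.write_json(manifest, outdir / "manifest.json")
    return manifest
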