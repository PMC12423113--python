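"""End-to-end pipeline: config validation, stage orchestration, artifacts.

Stage order mirrors the analysis design: quality filter -> Procrustes
superimposition + shape PCA -> inter-landmark distances + allometric size
adjustment -> measurement PCA + silhouette k-selection + k-means ->
MANOVA / post hoc tests -> discrimination correction -> tissue-switch
metrics -> WIC/BIC/TNW decompositions -> individual WIC + GLM.

Every stage writes a self-describing CSV artifact (column headers carry
units; size-adjusted measurements are explicitly log10(mm)) and the run
emits a machine-readable ``summary.json``.  All stochastic stages consume
sub-seeds derived from one master seed recorded in the summary, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import landmarks as lmio
from . import morphometry as morpho
from . import morphotyping as mtype
from . import isotopes as iso
from . import specialization as spec
from . import synthetic as synth

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid config:\n  " + "\n  ".join(errors))


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


_DEFAULTS: dict[str, dict[str, Any]] = {
    "quality": {"min_photo_rank": 2, "min_landmark_rank": 2},
    "morphometry": {"l_m_mm": None, "tol": 1e-8, "max_iter": 100},
    "clustering": {"n_pcs": 2, "k_range": [2, 3, 4, 5], "restarts": 50, "seed": 0},
    "discrimination": dataclasses.asdict(iso.DiscriminationFactors()),
    "specialization": {"direction": "plasma_on_rbc", "interactions": []},
}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted pipeline configuration.

    Exactly one of ``inputs`` (paths to TPS + specimen CSV + isotope CSV)
    or ``synthetic`` (SyntheticTruth keyword block) is present.
    """

    inputs: dict[str, str] | None = None
    synthetic: dict[str, Any] | None = None
    quality: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["quality"]))
    morphometry: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["morphometry"]))
    clustering: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["clustering"]))
    discrimination: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["discrimination"]))
    specialization: dict[str, Any] = field(default_factory=lambda: dict(_DEFAULTS["specialization"]))
    output_dir: str = "results/run"

    def emit(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def validate_config(source: str | Path | dict) -> PipelineConfig:
    """Validate a YAML config (path or already-parsed mapping).

    Fills all defaults, rejects unknown keys, and aggregates every error
    into one :class:`ConfigError` rather than failing at the first.
    """
    if isinstance(source, (str, Path)):
        raw = yaml.safe_load(Path(source).read_text())
    else:
        raw = dict(source)
    errors: list[str] = []
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(["config root must be a mapping"])

    known = set(_DEFAULTS) | {"inputs", "synthetic", "output_dir"}
    for key in raw:
        if key not in known:
            errors.append(f"unknown key {key!r}")

    has_inputs = raw.get("inputs") is not None
    has_synth = raw.get("synthetic") is not None
    if has_inputs and has_synth:
        errors.append("'inputs' and 'synthetic' are mutually exclusive")
    if not has_inputs and not has_synth:
        errors.append("one of 'inputs' or 'synthetic' is required")

    if has_inputs:
        required = {"tps", "specimens", "isotopes"}
        inp = raw["inputs"]
        if not isinstance(inp, dict):
            errors.append("'inputs' must be a mapping")
        else:
            for k in sorted(required - set(inp)):
                errors.append(f"inputs.{k} is required")
            for k in sorted(set(inp) - required):
                errors.append(f"unknown key inputs.{k}")
    if has_synth:
        truth_fields = {f.name for f in dataclasses.fields(synth.SyntheticTruth)}
        for k in sorted(set(raw["synthetic"]) - truth_fields):
            errors.append(f"unknown key synthetic.{k}")

    sections: dict[str, dict] = {}
    for name, defaults in _DEFAULTS.items():
        block = dict(defaults)
        user = raw.get(name, {})
        if not isinstance(user, dict):
            errors.append(f"{name!r} must be a mapping")
            user = {}
        for k in sorted(set(user) - set(defaults)):
            errors.append(f"unknown key {name}.{k}")
        block.update({k: v for k, v in user.items() if k in defaults})
        sections[name] = block

    if errors:
        raise ConfigError(errors)
    return PipelineConfig(
        inputs=raw.get("inputs"),
        synthetic=raw.get("synthetic"),
        output_dir=raw.get("output_dir", "results/run"),
        **sections,
    )


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        truth = synth.SyntheticTruth(**config.synthetic)
        configs, labels = synth.simulate_landmarks(truth)
        fish = synth.fish_table(truth)
        records = synth.simulate_isotopes(truth)
        records = records.drop(columns=["morphotype"])
        return configs, fish.rename(columns={"fish_id": "specimen_id"}), records, truth
    paths = config.inputs
    configs = lmio.read_tps(paths["tps"])
    specimens = pd.read_csv(paths["specimens"])
    records = pd.read_csv(paths["isotopes"])
    spec_meta = specimens.set_index("specimen_id")
    for cfg in configs:
        if cfg.specimen_id in spec_meta.index and "year" in spec_meta.columns:
            cfg.year = int(spec_meta.loc[cfg.specimen_id, "year"])
    if "fork_length_mm" not in records.columns:
        records = records.merge(
            specimens[["specimen_id", "fork_length_mm"]].rename(
                columns={"specimen_id": "fish_id"}
            ),
            on="fish_id",
            how="left",
        )
    return configs, specimens, records, None


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute the full analysis; returns the machine-readable summary.

    Artifacts (one CSV per stage + ``summary.json``) are written under
    ``outdir`` (default: the config's ``output_dir``).  Any stage failure
    raises :class:`PipelineStageError` naming the stage.
    """
    outdir = Path(outdir if outdir is not None else config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config": config.emit()}

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raised with stage name
                raise PipelineStageError(name, e) from e
        return wrap

    configs, specimens, records, truth = stage("load_inputs")(_load_inputs, config)
    summary["n_specimens_input"] = len(configs)

    retained, excluded = stage("quality_filter")(
        lmio.quality_filter, configs, **config.quality
    )
    retained = [c for c in retained if c.is_valid]
    pd.DataFrame([dataclasses.asdict(e) for e in excluded]).to_csv(
        outdir / "excluded_specimens.csv", index=False
    )
    summary["n_retained"] = len(retained)
    summary["n_excluded"] = len(excluded)

    def scale_all():
        return [lmio.apply_scale(c) if c.scale is not None and not c.scale_applied
                else c for c in retained]

    scaled = stage("apply_scale")(scale_all)

    aligned = stage("gpa")(
        morpho.gpa, scaled,
        tol=config.morphometry["tol"], max_iter=config.morphometry["max_iter"],
    )
    spca = stage("shape_pca")(morpho.shape_pca, aligned)
    summary["gpa"] = {
        "iterations": aligned.iterations_used,
        "converged": bool(aligned.converged),
    }
    summary["shape_pca_percent_variance"] = [
        round(float(v), 6) for v in spca.percent_variance[:5]
    ]

    table = stage("distances")(morpho.measurement_table, scaled)
    adjusted, slopes = stage("reist_adjust")(
        morpho.reist_adjust, table, l_m=config.morphometry["l_m_mm"]
    )
    adj_cols = {f"{m}_adj": f"{m}_adj_log10mm" for m in morpho.MEASUREMENTS}
    adjusted.rename(columns=adj_cols).to_csv(outdir / "measurements.csv", index=False)
    slopes.to_csv(outdir / "allometric_slopes.csv", header=["slope_b"])
    summary["l_m_mm"] = round(float(adjusted.attrs["l_m_mm"]), 6)

    adj_vars = tuple(f"{m}_adj" for m in morpho.MEASUREMENTS)
    mpca = stage("measurement_pca")(mtype.measurement_pca, adjusted, adj_vars)
    n_pcs = int(config.clustering["n_pcs"])
    scores = mpca.scores[:, :n_pcs]
    chosen_k, sil_table = stage("select_k")(
        mtype.select_k_silhouette, scores,
        k_range=tuple(config.clustering["k_range"]),
        restarts=int(config.clustering["restarts"]),
        seed=int(config.clustering["seed"]),
    )
    km = stage("kmeans")(
        mtype.kmeans_cluster, scores, chosen_k,
        restarts=int(config.clustering["restarts"]),
        seed=int(config.clustering["seed"]),
    )
    sil_table.to_csv(outdir / "silhouette_by_k.csv", index=False)
    assignments = pd.DataFrame(
        {"specimen_id": adjusted["specimen_id"], "cluster": km.assignments}
    )
    assignments.to_csv(outdir / "morphotype_assignments.csv", index=False)
    summary["measurement_pca_percent_variance"] = [
        round(float(v), 6) for v in mpca.percent_variance
    ]
    summary["chosen_k"] = chosen_k
    summary["cluster_sizes"] = {
        str(k): int(v) for k, v in zip(*np.unique(km.assignments, return_counts=True))
    }

    checks = stage("assumption_checks")(
        mtype.assumption_checks, adjusted, adj_vars, km.assignments
    )
    checks.to_csv(outdir / "assumption_checks.csv", index=False)
    manova = stage("manova")(mtype.manova_pillai, adjusted, adj_vars, km.assignments)
    summary["manova"] = {
        "pillai": round(manova.statistic, 6),
        "F": round(manova.f_statistic, 4),
        "df1": manova.df1,
        "df2": manova.df2,
        "p": float(manova.p_value),
    }
    posthoc = stage("posthoc")(
        mtype.posthoc_welch, adjusted, adj_vars, km.assignments, 9
    )
    posthoc.rows.to_csv(outdir / "posthoc_tests.csv", index=False)

    corrected = stage("discrimination")(
        iso.apply_discrimination, records,
        iso.DiscriminationFactors(**config.discrimination),
    )
    cluster_map = assignments.set_index("specimen_id")["cluster"]
    corrected["cluster"] = corrected["fish_id"].map(cluster_map)
    corrected = corrected.dropna(subset=["cluster"])
    corrected["cluster"] = corrected["cluster"].astype(int)
    corrected.to_csv(outdir / "isotopes_corrected.csv", index=False)

    switches = stage("tissue_switch")(iso.tissue_switch, corrected)
    switches.to_csv(outdir / "tissue_switches.csv", index=False)
    summary["n_paired_fish"] = len(switches)

    decomp = stage("variance_decomposition")(
        spec.decomposition_table, corrected, cluster_map
    )
    decomp.to_csv(outdir / "variance_decomposition.csv", index=False)
    summary["decomposition"] = [
        {k: (round(float(v), 6) if isinstance(v, (int, float, np.floating)) and k in
             ("WIC", "BIC", "TNW", "IS") else (int(v) if k in ("n_fish", "n_obs") else bool(v) if k == "boundary" else v))
         for k, v in row.items()}
        for row in decomp.to_dict("records")
    ]
    if truth is not None:
        summary["truth_is"] = round(synth.truth_is(truth), 6)

    wide = stage("paired_wide")(spec.paired_wide, corrected)
    glm_results = {}
    for isotope in ("d13C", "d15N"):
        wic = stage("individual_wic")(
            spec.individual_wic, wide, isotope,
            direction=config.specialization["direction"],
        )
        wic.to_csv(outdir / f"individual_wic_{isotope}.csv", index=False)
        if len(wic) >= 10 and wic["cluster"].nunique() > 1:
            res, coef, log = stage("wic_glm")(
                spec.simplify_by_aic, wic,
                tuple(config.specialization["interactions"]),
            )
            coef.to_csv(outdir / f"wic_glm_{isotope}.csv", index=False)
            glm_results[isotope] = {
                "aic": round(float(res.aic), 4),
                "terms": list(coef["term"]),
                "dropped": [d["term"] for d in log if d["action"] == "dropped"],
            }
    summary["wic_glm"] = glm_results

    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    logger.info("pipeline complete; artifacts in %s", outdir)
    return summary
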