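"""End-to-end pipeline: simulate -> normalize -> model -> subset -> cv -> compare.

A single config object (loadable from YAML) fixes every parameter and seed;
reruns with the same config produce byte-identical artifacts.  Two built-in
profiles exist: ``full`` keeps the study's settings (1000 stability runs,
10 CV repeats, 11-point alpha grid) and ``test`` scales them to desk-size
(100 runs, 1 repeat, lasso-only inner CV) while keeping the same structure.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import matrix as mio
from ._seeds import derive_seed
from .comparison import build_distance_matrix, hierarchical_cluster
from .cross_validation import ModelingConfig, lpocv_panel
from .elastic_net import ElasticNetCV
from .model_selection import lasso_stability, subset_sweep
from .normalization import normalize_pipeline
from .synthetic import InstrumentProfile, simulate_study, resample_counts

log = logging.getLogger("glycodrug")


class ConfigError(ValueError):
    pass


def _from_dict(cls, data: dict):
    """Build a dataclass from a dict, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{f.name: data[f.name] for f in dataclasses.fields(cls) if f.name in data})


@dataclass
class SimulateConfig:
    n_cell_lines: int = 22
    n_proteins: int = 185
    n_household: int = 7
    n_target_only: int = 4
    n_drugs: int = 10
    k_true: int = 3
    noise_sd: float = 0.4
    target_scale: float = 2.5
    target_offset: float = 1.0
    replicate_dispersion: float = 20.0


@dataclass
class NormalizationConfig:
    household_k: int = 7
    min_total: float = 100.0
    n_quantiles: int = 99


@dataclass
class RegressionConfig:
    alpha_grid: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    n_repeats: int = 10
    n_folds: int = 10
    tol: float = 1e-7
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    max_iter: int = 100_000


@dataclass
class StabilityConfig:
    n_runs: int = 1000
    n_folds: int = 10
    threshold: float = 1.0


@dataclass
class SubsetConfig:
    k_values: tuple = (1, 3)


@dataclass
class CVConfig:
    mode: str = "round-robin"
    alpha_grid: tuple = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))
    n_repeats: int = 3
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01


@dataclass
class PipelineConfig:
    seed: int = 0
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    normalization: NormalizationConfig = field(default_factory=NormalizationConfig)
    regression: RegressionConfig = field(default_factory=RegressionConfig)
    stability: StabilityConfig = field(default_factory=StabilityConfig)
    subset: SubsetConfig = field(default_factory=SubsetConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def __post_init__(self) -> None:
        if not (0 < self.normalization.min_total or self.normalization.min_total == 0):
            raise ConfigError("min_total must be >= 0")
        if self.stability.n_runs < 1 or self.regression.n_repeats < 1:
            raise ConfigError("run/repeat counts must be >= 1")
        if self.cv.mode not in ("round-robin", "pooled"):
            raise ConfigError(f"unknown cv mode {self.cv.mode!r}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        nested = {
            "simulate": SimulateConfig,
            "normalization": NormalizationConfig,
            "regression": RegressionConfig,
            "stability": StabilityConfig,
            "subset": SubsetConfig,
            "cv": CVConfig,
        }
        unknown = set(data) - set(nested) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict = {"seed": data.get("seed", 0)}
        for key, sub_cls in nested.items():
            if key in data:
                kwargs[key] = _from_dict(sub_cls, data[key] or {})
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def get_profile(profile: str, seed: int = 0) -> PipelineConfig:
    """Built-in configurations.

    ``full`` keeps the study's settings; ``test`` is the desk-scale profile
    (100 stability runs, coarse alpha grid, 1 CV repeat, lasso-only inner CV
    in the leave-pair-out stage) used by the default test suite.
    """
    if profile == "full":
        return PipelineConfig(seed=seed)
    if profile == "test":
        cfg = PipelineConfig(seed=seed)
        cfg.stability = StabilityConfig(n_runs=100, n_folds=5, threshold=1.0)
        cfg.regression = RegressionConfig(
            alpha_grid=(0.25, 0.5, 0.75, 1.0), n_repeats=3, n_folds=5, n_lambda=50
        )
        cfg.cv = CVConfig(
            mode="round-robin", alpha_grid=(1.0,), n_repeats=1, n_folds=5, n_lambda=30
        )
        return cfg
    raise ConfigError(f"unknown profile {profile!r}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages on synthetic data; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def record(stage: str, paths: list[Path]) -> None:
        manifest["stages"][stage] = {
            "outputs": {p.name: _sha256(p) for p in sorted(paths)},
            "seed": derive_seed(config.seed, stage),
        }
        log.info("stage %s: %d artifact(s)", stage, len(paths))

    # ---- simulate -------------------------------------------------------
    sim = config.simulate
    study = simulate_study(
        n_cell_lines=sim.n_cell_lines,
        n_proteins=sim.n_proteins,
        n_household=sim.n_household,
        n_target_only=sim.n_target_only,
        n_drugs=sim.n_drugs,
        k_true=sim.k_true,
        noise_sd=sim.noise_sd,
        target_profile=InstrumentProfile(
            scale=sim.target_scale, offset=sim.target_offset, label="target"
        ),
        seed=derive_seed(config.seed, "simulate"),
    )
    paths = []
    for name, df in (
        ("reference_counts.tsv", study.reference_counts),
        ("target_counts.tsv", study.target_counts),
        ("true_counts.tsv", study.true_counts),
    ):
        mio.write_counts_tsv(df, out / name)
        paths.append(out / name)
    mio.write_response_tsv(study.responses, out / "responses.tsv")
    paths.append(out / "responses.tsv")
    _write_json(
        {d: json.loads(t.to_json()) for d, t in study.truths.items()}, out / "truth.json"
    )
    paths.append(out / "truth.json")
    record("simulate", paths)

    # ---- normalize ------------------------------------------------------
    norm = config.normalization
    expression = normalize_pipeline(
        study.reference_counts,
        study.target_counts,
        study.target_only_cell_lines,
        household_k=norm.household_k,
        min_total=norm.min_total,
        n_quantiles=norm.n_quantiles,
    )
    mio.write_expression_tsv(expression, out / "expression.tsv")
    record("normalize", [out / "expression.tsv"])

    drugs = study.responses.loc[expression.index]

    # ---- model (elastic-net fit + lasso stability) ----------------------
    reg, stab = config.regression, config.stability
    models = {}
    stability_rows = []
    pools = {}
    for di, drug in enumerate(drugs.columns):
        est = ElasticNetCV(
            alpha_grid=reg.alpha_grid,
            n_repeats=reg.n_repeats,
            n_folds=reg.n_folds,
            n_lambda=reg.n_lambda,
            lambda_min_ratio=reg.lambda_min_ratio,
            tol=reg.tol,
            max_iter=reg.max_iter,
            seed=derive_seed(config.seed, "model", di),
        ).fit(expression, drugs[drug])
        models[drug] = est.model_.to_dict()
        table = lasso_stability(
            expression,
            drugs[drug],
            n_runs=stab.n_runs,
            n_folds=stab.n_folds,
            base_seed=derive_seed(config.seed, "stability", di),
            drug_id=drug,
            n_lambda=reg.n_lambda,
            lambda_min_ratio=reg.lambda_min_ratio,
        )
        pools[drug] = table
        for feat, fr in sorted(table.frequency.items()):
            stability_rows.append({"drug": drug, "feature": feat, "frequency": fr})
    _write_json(models, out / "models.json")
    pd.DataFrame(stability_rows, columns=["drug", "feature", "frequency"]).to_csv(
        out / "stability.tsv", sep="\t", index=False, float_format="%.10g"
    )
    record("model", [out / "models.json", out / "stability.tsv"])

    # ---- subset ---------------------------------------------------------
    sweep = subset_sweep(expression, drugs, k_values=tuple(config.subset.k_values), candidate_pools=pools)
    sweep.results.to_csv(out / "subsets.tsv", sep="\t", index=False, float_format="%.10g")
    _write_json(
        {
            "mean_r2": {str(k): v for k, v in sweep.mean_r2.items()},
            "histograms": {str(k): v for k, v in sweep.histograms.items()},
            "no_model_drugs": sweep.no_model_drugs,
        },
        out / "subset_summary.json",
    )
    record("subset", [out / "subsets.tsv", out / "subset_summary.json"])

    # ---- cv -------------------------------------------------------------
    cvc = config.cv
    mc = ModelingConfig(
        alpha_grid=tuple(cvc.alpha_grid),
        n_repeats=cvc.n_repeats,
        n_folds=cvc.n_folds,
        n_lambda=cvc.n_lambda,
        lambda_min_ratio=cvc.lambda_min_ratio,
    )
    cv_table = lpocv_panel(
        expression, drugs, config=mc, seed=derive_seed(config.seed, "cv"), mode=cvc.mode
    )
    cv_table.to_csv(out / "cv.tsv", sep="\t", index=False, float_format="%.10g")
    record("cv", [out / "cv.tsv"])

    # ---- compare --------------------------------------------------------
    # Three predictor datasets with planted structure: the primary expression
    # matrix, a technical replicate of the same truth, and an independent one.
    replicate_counts = resample_counts(
        study.true_counts, dispersion=sim.replicate_dispersion,
        seed=derive_seed(config.seed, "replicate"),
    )
    replicate_expr = np.log10(replicate_counts.to_numpy(dtype=float).T + 1.0)
    replicate_X = pd.DataFrame(
        replicate_expr, index=replicate_counts.columns, columns=replicate_counts.index
    )
    unrelated = simulate_study(
        n_cell_lines=sim.n_cell_lines,
        n_proteins=sim.n_proteins,
        n_household=sim.n_household,
        n_target_only=0,
        n_drugs=1,
        k_true=sim.k_true,
        noise_sd=sim.noise_sd,
        seed=derive_seed(config.seed, "unrelated"),
    )
    unrelated_X = pd.DataFrame(
        np.log10(unrelated.true_counts.to_numpy(dtype=float).T + 1.0),
        index=drugs.index,
        columns=unrelated.true_counts.index,
    )

    perf = {}
    perf["glyco"] = cv_table.set_index("drug")["mean_correlation"]
    for name, Xds in (("replicate", replicate_X.loc[drugs.index]), ("unrelated", unrelated_X)):
        tbl = lpocv_panel(
            Xds, drugs, config=mc, seed=derive_seed(config.seed, "compare", name), mode=cvc.mode
        )
        perf[name] = tbl.set_index("drug")["mean_correlation"]
    perf_df = pd.DataFrame(perf).T
    perf_df.index.name = "dataset"
    perf_df.to_csv(out / "performance.tsv", sep="\t", float_format="%.10g")

    dist = build_distance_matrix(perf_df)
    dist.to_csv(out / "distance.tsv", sep="\t", float_format="%.10g")
    tree = hierarchical_cluster(dist, linkage="complete")
    (out / "dendrogram.nwk").write_text(tree.newick + "\n")
    record("compare", [out / "performance.tsv", out / "distance.tsv", out / "dendrogram.nwk"])

    _write_json(manifest, out / "manifest.json")
    return manifest


def configure_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
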