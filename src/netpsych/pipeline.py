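"""End-to-end study analysis driven by one config object.

Stage order mirrors the study workflow: descriptives (with gender
comparisons), whole-sample network + centralities + bridge selection,
bootstrap stability, three network-comparison contrasts (gender, age
band, high/low schizotypy by median split of the SPQ total), and
bootstrapped consensus DAGs for the whole sample and the subgroups.
Each stage draws from its own seed substream keyed by the master seed,
so disabling or reconfiguring one stage never changes another stage's
numbers, and a rerun with the same config and seed reproduces the
report byte for byte.
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
from scipy import stats

from . import __version__
from ._rng import child_seed, stage_rng
from .centrality import centrality_table, select_bridge_nodes, tidy_table
from .datasets import QuestionnaireDataset
from .dag import bootstrap_arcs, consensus_network
from .ggm import EstimatorConfig, estimate_network
from .nct import median_split, nct_run
from .simulate import study_like_dataset
from .stability import (
    DEFAULT_DROP_GRID,
    bootstrap_edges,
    casedrop_bootstrap,
    cs_coefficient,
    difference_test,
)

__all__ = ["AnalysisConfig", "StudyReport", "descriptives", "welch_t_cohens_d",
           "run_study"]

log = logging.getLogger(__name__)

ALL_STAGES = ("descriptives", "network", "stability", "nct", "dag")


@dataclass(frozen=True)
class AnalysisConfig:
    """Every knob of the full study analysis, with the study defaults."""

    input_csv: str | None = None
    synthetic_n: int = 1019
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_min_ratio: float = 0.01
    bootstrap_B: int = 1000
    casedrop_B: int = 1000
    casedrop_grid: tuple[float, ...] = DEFAULT_DROP_GRID
    n_perm: int = 10000
    dag_B: int = 1000
    dag_restarts: int = 5
    dag_perturbations: int = 10
    bridge_percentile: float = 80.0
    edge_threshold: float = 0.85
    direction_threshold: float = 0.5
    cs_threshold: float = 0.7
    cs_confidence: float = 0.95
    gender_column: str = "gender"
    age_band_column: str = "age_band"
    median_split_community: str = "SPQ"
    outlier_sensitivity: bool = False
    outlier_z: float = 3.29
    stages: tuple[str, ...] = ALL_STAGES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("edge_threshold", "direction_threshold", "cs_threshold",
                     "cs_confidence"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if not 0 < self.bridge_percentile < 100:
            raise ValueError("bridge_percentile must be in (0,100)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        object.__setattr__(self, "stages", tuple(self.stages))
        object.__setattr__(self, "casedrop_grid", tuple(self.casedrop_grid))

    @property
    def estimator(self) -> EstimatorConfig:
        return EstimatorConfig(self.gamma, self.n_lambda, self.lambda_min_ratio)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        """Load from a YAML or JSON config file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        return cls(**raw)

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def descriptives(data: QuestionnaireDataset) -> pd.DataFrame:
    """Per-column minimum, maximum, mean, SD, skewness and excess kurtosis.

    Skewness is the adjusted Fisher-Pearson sample coefficient and
    kurtosis the sample-adjusted excess kurtosis — the definitions
    common statistics packages print.
    """
    s = data.scores
    return pd.DataFrame(
        {
            "minimum": s.min(),
            "maximum": s.max(),
            "mean": s.mean(),
            "sd": s.std(ddof=1),
            "skewness": s.skew(),
            "kurtosis": s.kurt(),
        }
    )


def welch_t_cohens_d(x_a, x_b) -> dict[str, float]:
    """Welch's two-sample t-test plus Cohen's d with pooled SD."""
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    if len(x_a) < 2 or len(x_b) < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = x_a.var(ddof=1), x_b.var(ddof=1)
    na, nb = len(x_a), len(x_b)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    res = stats.ttest_ind(x_a, x_b, equal_var=False)
    return {
        "t": float(res.statistic),
        "df": float(res.df),
        "p": float(res.pvalue),
        "d": float((x_a.mean() - x_b.mean()) / np.sqrt(sp2)),
    }


@dataclass
class StudyReport:
    """JSON-serializable bundle of every stage's outputs."""

    report: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(_jsonable(self.report), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.reset_index().to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    return obj


def _load_data(config: AnalysisConfig) -> QuestionnaireDataset:
    if config.input_csv:
        return QuestionnaireDataset.from_csv(config.input_csv)
    rng = stage_rng(config.seed, "simulate")
    return study_like_dataset(config.synthetic_n, seed=child_seed(rng))


def _drop_outliers(data: QuestionnaireDataset, z_cut: float) -> QuestionnaireDataset:
    X = data.values()
    Z = np.abs((X - X.mean(axis=0)) / X.std(axis=0, ddof=1))
    keep = ~(Z > z_cut).any(axis=1)
    return data.subset(keep)


def _community_total(data: QuestionnaireDataset, community: str) -> np.ndarray:
    cols = [c for c in data.node_names if data.communities.get(c) == community]
    if not cols:
        raise ValueError(f"no columns in community {community!r}")
    return data.scores[cols].sum(axis=1).to_numpy(dtype=float)


def _network_block(data, config):
    net = estimate_network(data, config.estimator)
    table = centrality_table(net, data)
    return net, {
        "edges": net.edge_list(),
        "global_strength": net.global_strength(),
        "centrality": tidy_table(table),
        "bridge_nodes": select_bridge_nodes(table, config.bridge_percentile),
        "mean_predictability": float(table["predictability"].mean()),
    }


def run_study(
    config: AnalysisConfig, out_dir: str | Path | None = None
) -> StudyReport:
    """Run every enabled stage and return (and optionally write) the report.

    With ``out_dir`` set, each stage's JSON is written as soon as the
    stage completes, so a failing later stage preserves earlier outputs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "config": asdict(config),
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "package_version": __version__,
        }
    }

    def _emit(stage, payload):
        report[stage] = payload
        if out is not None:
            (out / f"{stage}.json").write_text(
                json.dumps(_jsonable(payload), indent=2, sort_keys=True)
            )
        log.info("[%s] done", stage)

    data = _load_data(config)
    if out is not None:
        data.to_csv(out / "data.csv")

    try:
        if "descriptives" in config.stages:
            block = {"table": descriptives(data)}
            if data.groups is not None and config.gender_column in data.groups:
                split = data.split_by(config.gender_column)
                if len(split) == 2:
                    (la, ga), (lb, gb) = sorted(split.items())
                    block["gender_levels"] = [la, lb]
                    block["gender_tests"] = {
                        node: welch_t_cohens_d(
                            ga.scores[node], gb.scores[node]
                        )
                        for node in data.node_names
                    }
            _emit("descriptives", block)

        if "network" in config.stages:
            net, block = _network_block(data, config)
            if config.outlier_sensitivity:
                trimmed = _drop_outliers(data, config.outlier_z)
                _, sens = _network_block(trimmed, config)
                block["outlier_sensitivity"] = {
                    "n_retained": trimmed.n, **sens,
                }
            _emit("network", block)

        if "stability" in config.stages:
            rng = stage_rng(config.seed, "bootstrap_edges")
            boot = bootstrap_edges(
                data, config.estimator, B=config.bootstrap_B, seed=child_seed(rng)
            )
            rng = stage_rng(config.seed, "casedrop")
            drop = casedrop_bootstrap(
                data, config.estimator, proportions=config.casedrop_grid,
                B=config.casedrop_B, seed=child_seed(rng),
            )
            cs = cs_coefficient(drop, config.cs_threshold, config.cs_confidence)
            diff_kinds = ["edge", "strength", "EI"]
            if data.communities:
                diff_kinds.append("bridge_EI")
            _emit("stability", {
                "edge_ci": boot.summary(),
                "cs_coefficients": cs,
                "difference_significant_counts": {
                    kind: int(difference_test(boot, kind).to_numpy().sum() // 2)
                    for kind in diff_kinds
                },
            })

        if "nct" in config.stages:
            block = {}
            for stage_key, label, splitter in _nct_contrasts(data, config):
                try:
                    d_a, d_b = splitter()
                except Exception as err:  # contrast unavailable for this data
                    block[label] = {"skipped": str(err)}
                    continue
                rng = stage_rng(config.seed, stage_key)
                res = nct_run(
                    d_a, d_b, config.estimator, n_perm=config.n_perm,
                    seed=child_seed(rng),
                )
                block[label] = res.to_dict()
            _emit("nct", block)

        if "dag" in config.stages:
            rng = stage_rng(config.seed, "dag")
            whole = bootstrap_arcs(
                data, B=config.dag_B, restarts=config.dag_restarts,
                perturbations=config.dag_perturbations, seed=child_seed(rng),
            )
            block = {"whole_sample": _consensus_block(whole, config)}
            rng = stage_rng(config.seed, "dag_subgroups")
            for label, sub in _dag_subgroups(data, config):
                tab = bootstrap_arcs(
                    sub, B=config.dag_B, restarts=config.dag_restarts,
                    perturbations=config.dag_perturbations, seed=child_seed(rng),
                )
                block[label] = _consensus_block(tab, config)
            _emit("dag", block)
    except Exception as err:
        raise RuntimeError(f"stage failure: {err}") from err

    rep = StudyReport(report)
    if out is not None:
        rep.to_json(out / "report.json")
    return rep


def _consensus_block(table, config):
    cons = consensus_network(
        table, config.edge_threshold, config.direction_threshold
    )
    return {
        "arcs": cons.arcs,
        "undirected_pairs": cons.undirected_pairs,
        "listing_ge_50": cons.listing,
    }


def _nct_contrasts(data, config):
    def by_group(column):
        def split():
            groups = data.split_by(column)
            if len(groups) != 2:
                raise ValueError(f"{column!r} does not define two groups")
            (_, a), (_, b) = sorted(groups.items())
            return a, b
        return split

    def by_median():
        total = _community_total(data, config.median_split_community)
        return median_split(data, total)

    yield "nct_gender", f"gender:{config.gender_column}", by_group(config.gender_column)
    yield "nct_age", f"age:{config.age_band_column}", by_group(config.age_band_column)
    yield ("nct_schizotypy", f"median_split:{config.median_split_community}",
           by_median)


def _dag_subgroups(data, config):
    if data.groups is not None and config.age_band_column in data.groups:
        for label, sub in sorted(data.split_by(config.age_band_column).items()):
            yield f"age:{label}", sub
    try:
        total = _community_total(data, config.median_split_community)
        low, high = median_split(data, total)
        yield f"{config.median_split_community}:low", low
        yield f"{config.median_split_community}:high", high
    except ValueError:
        return
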