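"""End-to-end pipeline: configuration, stage driver, artifact writing.

The pipeline ties the stages together: input loading and QC, per-method
posterior calibration, fold-network construction (static sweep, dynamic
sequence, consensus), network analysis (centralities, communities,
statistics, pivotal folds) and the fold-age analyses.  A run is
deterministic given its configuration and seeds; the manifest records
versions, seeds and per-stage counts so every output is re-derivable.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

import foldbridges
from foldbridges import ages as ages_mod
from foldbridges import analysis, networks, qc, synthetic
from foldbridges.calibration import BridgeCalibration, ScoreTable, write_threshold_table

STAGES = ("qc", "calibrate", "build", "analyze", "ages")


@dataclass
class PipelineConfig:
    annotation: str = "annotation.tsv"
    #: method name -> score TSV path
    scores: dict[str, str] = field(default_factory=dict)
    #: method name -> "similarity" | "distance"
    orientations: dict[str, str] = field(default_factory=dict)
    #: method name -> weight convention (defaults by orientation)
    weight_conventions: dict[str, str] = field(default_factory=dict)
    ages: str | None = "ages.tsv"
    coordinates: str | None = None
    domain_records: str | None = None  # aerospaci table for the QC stage
    thresholds: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    dynamic_grid: tuple[float, float, float] = (1.0, 0.5, 0.01)  # start, stop, step
    age_threshold: float = 0.6
    alpha: float = 0.01
    louvain_seed: int = 0
    louvain_restarts: int = 10
    aerospaci_min: float = qc.DEFAULT_AEROSPACI_MIN
    gap_threshold: float = qc.DEFAULT_GAP_THRESHOLD
    outdir: str = "foldbridges_out"
    base_dir: str = "."

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        for key in ("thresholds", "dynamic_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.base_dir = str(pathlib.Path(path).parent)
        return cfg

    def _path(self, p: str) -> pathlib.Path:
        q = pathlib.Path(p)
        return q if q.is_absolute() else pathlib.Path(self.base_dir) / q

    def validate(self, need_ages: bool = True) -> None:
        ts = self.thresholds
        if not ts or list(ts) != sorted(ts) or min(ts) <= 0 or max(ts) > 1:
            raise ValueError("thresholds must be sorted and lie in (0, 1]")
        if not self.scores:
            raise ValueError("no score tables configured")
        missing = [
            str(self._path(p))
            for p in [self.annotation, *self.scores.values()]
            if not self._path(p).exists()
        ]
        if need_ages:
            if self.ages is None:
                raise ValueError("age analysis enabled but no ages file configured")
            if not self._path(self.ages).exists():
                missing.append(str(self._path(self.ages)))
        if missing:
            raise ValueError(f"missing input files: {missing}")
        for m in self.scores:
            if self.orientations.get(m, "similarity") not in ("similarity", "distance"):
                raise ValueError(f"invalid orientation for method {m!r}")

    def convention_for(self, method: str) -> str:
        if method in self.weight_conventions:
            return self.weight_conventions[method]
        orientation = self.orientations.get(method, "similarity")
        return "inverse_distance" if orientation == "distance" else "score"


# ---------------------------------------------------------------------------
# IO helpers


def read_annotation(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"domain_id", "family", "superfamily", "fold", "class"}
    if not required <= set(df.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    return df


def read_score_table(path, method: str, orientation: str) -> ScoreTable:
    df = pd.read_csv(path, sep="\t")
    score_columns = [c for c in df.columns if c not in ("domain_i", "domain_j")]
    return ScoreTable(df, method=method, orientation=orientation, score_columns=score_columns)


def read_ages(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    ages_mod.validate_ages(df)
    return df


# ---------------------------------------------------------------------------
# simulate


def simulate(spec: synthetic.SyntheticSpec, outdir, coordinate_fixtures: int = 0) -> PipelineConfig:
    """Write a synthetic input bundle plus a ready-to-run configuration."""
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = synthetic.generate(spec)
    bundle.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    bundle.ages.to_csv(out / "ages.tsv", sep="\t", index=False)
    bundle.bridges.to_csv(out / "planted_bridges.tsv", sep="\t", index=False)
    bundle.communities.rename_axis("fold").reset_index().to_csv(
        out / "planted_communities.tsv", sep="\t", index=False
    )
    scores = {}
    orientations = {}
    for name, table in bundle.score_tables.items():
        fname = f"scores_{name}.tsv"
        table.frame.to_csv(out / fname, sep="\t", index=False)
        scores[name] = fname
        orientations[name] = table.orientation
    if coordinate_fixtures:
        synthetic.generate_coordinate_fixtures(
            coordinate_fixtures, 0.1, 0.1, spec.seed, out_dir=out / "coords"
        )
    cfg = PipelineConfig(
        annotation="annotation.tsv",
        scores=scores,
        orientations=orientations,
        ages="ages.tsv",
        outdir="results",
        base_dir=str(out),
    )
    payload = {
        k: v
        for k, v in dataclasses.asdict(cfg).items()
        if k != "base_dir" and v not in (None, {}, ())
    }
    payload["thresholds"] = list(cfg.thresholds)
    payload["dynamic_grid"] = list(cfg.dynamic_grid)
    (out / "config.yaml").write_text(yaml.safe_dump(payload, sort_keys=True))
    return cfg


def spec_from_yaml(path) -> synthetic.SyntheticSpec:
    """Build a SyntheticSpec from a declarative YAML file.

    Scalar fields of :class:`foldbridges.synthetic.SyntheticSpec` may be
    set; ``preset: strong_community`` selects the well-separated community
    validation preset.
    """
    raw = yaml.safe_load(pathlib.Path(path).read_text()) or {}
    preset = raw.pop("preset", None)
    base = (
        synthetic.strong_community_spec()
        if preset == "strong_community"
        else synthetic.SyntheticSpec()
    )
    known = {f.name for f in dataclasses.fields(synthetic.SyntheticSpec)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown synthetic-spec fields: {sorted(unknown)}")
    if "domains_per_fold" in raw and isinstance(raw["domains_per_fold"], list):
        raw["domains_per_fold"] = tuple(raw["domains_per_fold"])
    spec = dataclasses.replace(base, **raw)
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# in-memory convenience API


def calibrate_and_collapse(
    score_tables: dict, annotation: pd.DataFrame, conventions: dict | None = None
) -> tuple[dict, dict]:
    """Calibrate each method and collapse posteriors to fold level in memory.

    Returns ``(calibration_results, collapsed_tables)`` keyed by method.
    Pairs with posterior below 0.5 are dropped before the collapse — they can
    never become edges at the thresholds in use.
    """
    alpha_of = annotation.set_index("domain_id")["class"] == "a"
    results, collapsed = {}, {}
    for method, table in score_tables.items():
        result = BridgeCalibration.from_score_table(table, annotation).fit()
        results[method] = result
        pairs = table.frame[["domain_i", "domain_j"]].copy()
        pairs["score"] = table.frame[result.score_column]
        alpha = (
            pairs["domain_i"].map(alpha_of) | pairs["domain_j"].map(alpha_of)
        ).to_numpy()
        pairs["posterior"] = result.posterior(pairs["score"].to_numpy(), alpha)
        pairs = pairs[pairs["posterior"] >= 0.5]
        convention = (conventions or {}).get(
            method,
            "inverse_distance" if table.orientation == "distance" else "score",
        )
        pairs = networks.assign_weights(pairs, convention)
        collapsed[method] = networks.collapse(pairs, annotation, level="fold")
    return results, collapsed


def method_networks(
    score_tables: dict,
    annotation: pd.DataFrame,
    threshold: float,
    ages: pd.DataFrame | None = None,
    include_consensus: bool = False,
) -> dict:
    """Per-method fold networks at one threshold, optionally plus consensus."""
    _, collapsed = calibrate_and_collapse(score_tables, annotation)
    nets = {
        m: networks.build_static_network(c, annotation, threshold, m, ages=ages)
        for m, c in collapsed.items()
    }
    if include_consensus:
        nets["consensus"] = networks.build_consensus(nets)
    return nets


# ---------------------------------------------------------------------------
# pipeline driver


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the configured stages, writing artifacts and a manifest.

    Stage errors leave completed outputs in place together with a
    ``FAILED_<stage>`` marker, then re-raise.
    """
    need_ages = "ages" in stages
    config.validate(need_ages=need_ages)
    out = pathlib.Path(config.base_dir) / config.outdir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": foldbridges.__version__,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "config": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("base_dir",)
        },
        "stages": {},
    }
    state: dict = {}
    for stage in STAGES:
        if stage not in stages:
            continue
        try:
            counts = _STAGE_FUNCS[stage](config, out, state)
        except Exception as exc:
            (out / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
            raise
        manifest["stages"][stage] = counts
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def _stage_qc(config: PipelineConfig, out: pathlib.Path, state: dict) -> dict:
    annotation = read_annotation(config._path(config.annotation))
    counts = {"n_domains_in": len(annotation)}
    if config.domain_records is not None:
        records = pd.read_csv(config._path(config.domain_records), sep="\t")
        coord_dir = config._path(config.coordinates) if config.coordinates else None
        retained, log = qc.apply_qc(
            records, coord_dir, config.aerospaci_min, config.gap_threshold
        )
        log.to_csv(out / "qc_rejections.tsv", sep="\t", index=False)
        keep = set(retained["domain_id"])
        annotation = annotation[annotation["domain_id"].isin(keep)].reset_index(drop=True)
        counts.update(n_rejected=len(log), n_domains_out=len(annotation))
    state["annotation"] = annotation
    counts["n_folds"] = int(annotation["fold"].nunique())
    return counts


def _stage_calibrate(config: PipelineConfig, out: pathlib.Path, state: dict) -> dict:
    annotation = state.get("annotation")
    if annotation is None:
        annotation = read_annotation(config._path(config.annotation))
        state["annotation"] = annotation
    results = {}
    pair_tables = {}
    counts = {}
    for method, path in config.scores.items():
        table = read_score_table(
            config._path(path), method, config.orientations.get(method, "similarity")
        )
        result = BridgeCalibration.from_score_table(table, annotation).fit()
        results[method] = result
        alpha_of = annotation.set_index("domain_id")["class"] == "a"
        alpha_involved = (
            table.frame["domain_i"].map(alpha_of) | table.frame["domain_j"].map(alpha_of)
        ).to_numpy()
        pairs = table.frame[["domain_i", "domain_j"]].copy()
        pairs["score"] = table.frame[result.score_column]
        pairs["posterior"] = result.posterior(pairs["score"].to_numpy(), alpha_involved)
        pairs = networks.assign_weights(pairs, config.convention_for(method))
        pair_tables[method] = pairs
        counts[method] = {
            "n_pairs": len(pairs),
            "score_column": result.score_column,
            "prior_same_fold_other": result.partitions["other"].prior_same_fold,
        }
    write_threshold_table(results.values(), out / "threshold_table.tsv", config.thresholds)
    state["calibrations"] = results
    state["pair_tables"] = pair_tables
    return counts


def _stage_build(config: PipelineConfig, out: pathlib.Path, state: dict) -> dict:
    annotation = state["annotation"]
    ages_df = read_ages(config._path(config.ages)) if config.ages else None
    collapsed = {
        m: networks.collapse(pairs, annotation, level="fold")
        for m, pairs in state["pair_tables"].items()
    }
    suite = networks.static_network_sweep(
        collapsed, annotation, config.thresholds, ages=ages_df
    )
    net_dir = out / "networks"
    net_dir.mkdir(exist_ok=True)
    for (method, t), G in suite.items():
        stem = f"{method}_t{t:.2f}"
        networks.write_graphml(G, net_dir / f"{stem}.graphml")
        networks.write_edge_list(G, net_dir / f"{stem}.edges.tsv")
    start, stop, step = config.dynamic_grid
    grid = np.round(np.arange(start, stop - 1e-9, -step), 10)
    dyn_counts = {}
    for method, coll in collapsed.items():
        birth, _ = networks.build_dynamic_sequence(
            coll, annotation, method, grid=grid, ages=ages_df
        )
        birth.to_csv(net_dir / f"{method}_dynamic_birth.tsv", sep="\t", index=False)
        final = networks.build_static_network(coll, annotation, grid[-1], method, ages=ages_df)
        for u, v, d in final.edges(data=True):
            key = (min(u, v), max(u, v))
            row = birth[(birth["group_a"] == key[0]) & (birth["group_b"] == key[1])]
            d["birth_threshold"] = float(row["birth_threshold"].iloc[0])
        networks.write_graphml(final, net_dir / f"{method}_dynamic.graphml")
        dyn_counts[method] = int(birth["birth_threshold"].notna().sum())
    state["collapsed"] = collapsed
    state["suite"] = suite
    state["ages_df"] = ages_df
    return {
        "n_static_networks": len(suite),
        "edges_per_network": {f"{m}@{t}": G.number_of_edges() for (m, t), G in suite.items()},
        "dynamic_edges": dyn_counts,
    }


def _stage_analyze(config: PipelineConfig, out: pathlib.Path, state: dict) -> dict:
    suite = state["suite"]
    ana_dir = out / "analysis"
    ana_dir.mkdir(exist_ok=True)
    centrality_tables = {}
    partitions_by_network = {}
    stats_rows = []
    community_rows = []
    for (method, t), G in suite.items():
        network_id = f"{method}@{t:.2f}"
        cent = analysis.centralities(G)
        parts = analysis.partition_central_peripheral(G, cent)
        centrality_tables[network_id] = analysis.centrality_table(G, cent, parts)
        partitions_by_network[network_id] = parts
        siblings = [
            H for (m2, t2), H in suite.items() if t2 == t and m2 not in (method, "consensus")
        ] if method != "consensus" else []
        stats = analysis.network_statistics(G, siblings)
        stats_rows.append({"network": network_id, "method": method, "threshold": t, **stats})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            part = analysis.detect_communities(
                G, seed=config.louvain_seed, restarts=config.louvain_restarts, network_id=network_id
            )
        for node, lab in sorted(part.labels.items()):
            community_rows.append(
                {"network": network_id, "node": node, "community": lab, "modularity": part.modularity}
            )
    pd.concat(centrality_tables.values(), keys=centrality_tables.keys(), names=["network"]).reset_index(
        level=0
    ).to_csv(ana_dir / "centralities.tsv", sep="\t", index=False)
    pd.DataFrame(stats_rows).to_csv(ana_dir / "network_statistics.tsv", sep="\t", index=False)
    pd.DataFrame(community_rows).to_csv(ana_dir / "communities.tsv", sep="\t", index=False)
    pivotal = analysis.identify_pivotal(partitions_by_network.values())
    (ana_dir / "pivotal_folds.txt").write_text("\n".join(sorted(pivotal)) + "\n")
    state["partitions_by_network"] = partitions_by_network
    return {
        "n_networks_analyzed": len(suite),
        "n_pivotal": len(pivotal),
        "pivotal": sorted(pivotal),
    }


def _stage_ages(config: PipelineConfig, out: pathlib.Path, state: dict) -> dict:
    ages_df = state.get("ages_df")
    if ages_df is None:
        ages_df = read_ages(config._path(config.ages))
    age_dir = out / "age_analysis"
    age_dir.mkdir(exist_ok=True)
    t = config.age_threshold
    per_method = {
        m: G for (m, t2), G in state["suite"].items() if t2 == t and m != "consensus"
    }
    mult, hist = networks.edge_multiplicity(per_method)
    frame, summary, excluded = ages_mod.edge_age_differences(mult, ages_df)
    summary.to_csv(age_dir / "age_difference_by_multiplicity.tsv", sep="\t", index=False)
    frame.to_csv(age_dir / "pair_age_differences.tsv", sep="\t", index=False)
    report = ages_mod.central_peripheral_age_report(
        state["partitions_by_network"], ages_df, alpha=config.alpha
    )
    report.to_csv(age_dir / "central_peripheral_ages.tsv", sep="\t", index=False)
    return {
        "multiplicity_histogram": hist,
        "n_excluded_folds": len(excluded),
        "n_central_older": int(report["central_older"].sum()),
        "n_comparisons": int(report["tested"].sum()),
    }


_STAGE_FUNCS = {
    "qc": _stage_qc,
    "calibrate": _stage_calibrate,
    "build": _stage_build,
    "analyze": _stage_analyze,
    "ages": _stage_ages,
}
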