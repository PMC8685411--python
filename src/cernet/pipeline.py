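"""End-to-end orchestration: simulate -> DE -> coexpression -> ceRNA ->
enrichment -> qPCR, with a machine-readable run report.

Every stage writes deterministic TSV artifacts into the run directory
under fixed names (module constants below); a later stage whose inputs
are not in memory reloads them from those files, so stages can also be
run one at a time. The report tallies DE counts per class (total = up +
down), coexpression pairs, triplets and the network summary.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as cio
from .cerna import FilterConfig, build_network, find_triplets
from .coexpr import coexpression_pairs
from .diffexpr import ThresholdConfig, call_de, de_counts
from .enrichment import ora
from .errors import DesignError, ValidationError
from .matrix import RNA_CLASSES
from .qpcr import qpcr_report
from .simulate import SimulationConfig, simulate_annotation, simulate_expression, \
    simulate_qpcr, simulate_target_map

STAGES = ("simulate", "de", "coexpr", "cerna", "enrich", "qpcr")

EXPR_FILE = "expr_{cls}.tsv"
META_FILE = "samples.tsv"
DE_FILE = "de_{cls}.tsv"
TARGETS_FILE = "target_map.tsv"
GMT_FILE = "annotation.gmt"
TRUTH_LABELS_FILE = "truth_labels.tsv"
TRUTH_TRIPLETS_FILE = "truth_triplets.tsv"
CT_FILE = "qpcr_ct.tsv"
PAIRS_FILE = "pairs.tsv"
TRIPLETS_FILE = "triplets.tsv"
SIF_FILE = "network.sif"
GRAPHML_FILE = "network.graphml"
NODES_FILE = "network_nodes.tsv"
EDGES_FILE = "network_edges.tsv"
ENRICH_FILE = "enrichment.tsv"
QPCR_FILE = "qpcr_results.tsv"
REPORT_FILE = "report.json"


@dataclass
class RunConfig:
    outdir: str = "cernet_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: ThresholdConfig = field(default_factory=ThresholdConfig)
    filters: FilterConfig = field(default_factory=FilterConfig)
    r_threshold: float = 0.8
    coexpr_p_threshold: float = 0.05
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    make_plots: bool = False

    def __post_init__(self):
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")
        for s in STAGES:
            self.stages.setdefault(s, True)
        # one seed drives every generator
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = dict(raw)
        for key, sub in (("simulation", SimulationConfig),
                         ("thresholds", ThresholdConfig),
                         ("filters", FilterConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        raw = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


class _State:
    """Artifacts produced so far, reloadable from the run directory."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.matrices = None
        self.truth = None
        self.targets = None
        self.collection = None
        self.ct_table = None
        self.de_tables = None
        self.pairs = None
        self.triplets = None
        self.network = None

    def _require(self, name: str, value, filename: str):
        if value is None:
            raise DesignError(
                f"stage input {name!r} missing: expected artifact "
                f"{self.outdir / filename} (run the earlier stage first)"
            )
        return value

    def need_matrices(self):
        if self.matrices is None:
            loaded = {}
            for cls in RNA_CLASSES:
                expr = self.outdir / EXPR_FILE.format(cls=cls)
                meta = self.outdir / META_FILE
                if expr.exists() and meta.exists():
                    loaded[cls] = cio.read_expression(expr, meta, cls)
            self.matrices = loaded or None
        return self._require("expression matrices", self.matrices, EXPR_FILE.format(cls="*"))

    def need_de_tables(self):
        if self.de_tables is None:
            loaded = {}
            for cls in RNA_CLASSES:
                path = self.outdir / DE_FILE.format(cls=cls)
                if path.exists():
                    loaded[cls] = cio.read_de_table(path)
            self.de_tables = loaded or None
        return self._require("DE tables", self.de_tables, DE_FILE.format(cls="*"))

    def need_pairs(self):
        if self.pairs is None:
            path = self.outdir / PAIRS_FILE
            if path.exists():
                self.pairs = cio.read_tsv(path, numeric=["r", "p", "n", "mrna_log2fc"])
        return self._require("coexpression pairs", self.pairs, PAIRS_FILE)

    def need_targets(self):
        if self.targets is None:
            path = self.outdir / TARGETS_FILE
            if path.exists():
                self.targets = cio.read_target_map(path)
        return self._require("target map", self.targets, TARGETS_FILE)

    def need_collection(self):
        if self.collection is None:
            path = self.outdir / GMT_FILE
            if path.exists():
                self.collection = cio.read_gmt(path)
        return self._require("gene-set annotation", self.collection, GMT_FILE)

    def need_ct_table(self):
        if self.ct_table is None:
            path = self.outdir / CT_FILE
            if path.exists():
                self.ct_table = cio.read_ct_table(path)
        return self._require("qPCR Ct table", self.ct_table, CT_FILE)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _State(outdir)
    report: dict = {"seed": config.seed, "stages": [s for s in STAGES if config.stages[s]]}

    if config.stages["simulate"]:
        _stage_simulate(config, state, report)
    if config.stages["de"]:
        _stage_de(config, state, report)
    if config.stages["coexpr"]:
        _stage_coexpr(config, state, report)
    if config.stages["cerna"]:
        _stage_cerna(config, state, report)
    if config.stages["enrich"]:
        _stage_enrich(config, state, report)
    if config.stages["qpcr"]:
        _stage_qpcr(config, state, report)

    with open(outdir / REPORT_FILE, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def _stage_simulate(config: RunConfig, state: _State, report: dict) -> None:
    matrices, truth = simulate_expression(config.simulation)
    targets = simulate_target_map(config.simulation, truth)
    collection = simulate_annotation(config.simulation, truth)
    ct = simulate_qpcr(config.simulation, truth)
    state.truth = truth

    out = state.outdir
    for cls, matrix in matrices.items():
        cio.write_expression(matrix, out / EXPR_FILE.format(cls=cls))
    cio.write_metadata(next(iter(matrices.values())).samples, out / META_FILE)
    cio.write_target_map(targets, out / TARGETS_FILE)
    cio.write_gmt(collection, out / GMT_FILE)
    cio.write_truth_labels(truth, out / TRUTH_LABELS_FILE)
    cio.write_truth_triplets(truth, out / TRUTH_TRIPLETS_FILE)
    cio.write_ct_table(ct, out / CT_FILE)
    # downstream stages consume the persisted artifacts, so a full run and a
    # stage-at-a-time run see byte-identical inputs
    state.matrices = {
        cls: cio.read_expression(out / EXPR_FILE.format(cls=cls), out / META_FILE, cls)
        for cls in matrices
    }
    state.targets = cio.read_target_map(out / TARGETS_FILE)
    state.collection = cio.read_gmt(out / GMT_FILE)
    state.ct_table = cio.read_ct_table(out / CT_FILE)
    report["simulate"] = {
        "n_samples": 2 * config.simulation.n_per_group,
        "features": {cls: len(m.features) for cls, m in matrices.items()},
        "n_planted_triplets": len(truth.triplets),
    }


def _stage_de(config: RunConfig, state: _State, report: dict) -> None:
    matrices = state.need_matrices()
    tables = {}
    for cls, matrix in matrices.items():
        table = call_de(matrix, config.thresholds)
        tables[cls] = table
        cio.write_de_table(table, state.outdir / DE_FILE.format(cls=cls))
        if config.make_plots:
            from . import plots
            plots.volcano_plot(table, state.outdir / f"volcano_{cls}.png",
                               config.thresholds.lfc_threshold, config.thresholds.p_threshold)
            plots.de_heatmap(matrix, table, state.outdir / f"heatmap_{cls}.png")
    state.de_tables = tables
    report["de"] = {cls: de_counts(t) for cls, t in sorted(tables.items())}


def _stage_coexpr(config: RunConfig, state: _State, report: dict) -> None:
    matrices = state.need_matrices()
    tables = state.need_de_tables()
    frames = []
    for cls in ("lncRNA", "circRNA"):
        if cls in matrices and "mRNA" in matrices:
            frames.append(
                coexpression_pairs(
                    tables["mRNA"], tables[cls], matrices["mRNA"], matrices[cls],
                    r_threshold=config.r_threshold, p_threshold=config.coexpr_p_threshold,
                    pseudocount=config.thresholds.pseudocount,
                )
            )
    pairs = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    state.pairs = pairs
    cio.write_tsv(pairs, state.outdir / PAIRS_FILE)
    report["coexpression"] = {
        "n_pairs": int(len(pairs)),
        "n_positive": int((pairs["r"] > 0).sum()) if len(pairs) else 0,
    }


def _stage_cerna(config: RunConfig, state: _State, report: dict) -> None:
    tables = state.need_de_tables()
    pairs = state.need_pairs()
    targets = state.need_targets()
    matrices = state.need_matrices()
    triplets = find_triplets(tables, pairs, targets, config.filters, matrices)
    network = build_network(triplets)
    state.triplets, state.network = triplets, network
    out = state.outdir
    cio.write_tsv(triplets, out / TRIPLETS_FILE)
    cio.write_sif(network, out / SIF_FILE)
    cio.write_graphml(network, out / GRAPHML_FILE)
    cio.write_network_tsv(network, out / NODES_FILE, out / EDGES_FILE)
    report["cerna"] = network.summary


def _stage_enrich(config: RunConfig, state: _State, report: dict) -> None:
    tables = state.need_de_tables()
    collection = state.need_collection()
    matrices = state.need_matrices()
    annotated = set().union(*(gs.genes for gs in collection))
    universe = set(matrices["mRNA"].features) & annotated
    de_set = set(tables["mRNA"].loc[tables["mRNA"]["passes"], "feature"]) & universe
    records = ora(de_set, universe, collection)
    cio.write_tsv(records, state.outdir / ENRICH_FILE)
    report["enrichment"] = {
        "n_terms_tested": int(len(records)),
        "top_term": records["term"].iloc[0] if len(records) else None,
        "top_p": float(records["p"].iloc[0]) if len(records) else None,
    }


def _stage_qpcr(config: RunConfig, state: _State, report: dict) -> None:
    ct = state.need_ct_table()
    genes = sorted(set(ct["gene"]) - {"ACTB"})
    results = qpcr_report(ct, genes, reference="ACTB")
    cio.write_tsv(results, state.outdir / QPCR_FILE)
    report["qpcr"] = {
        row.gene: {"p": float(row.p), "direction": row.direction}
        for row in results.itertuples(index=False)
    }
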