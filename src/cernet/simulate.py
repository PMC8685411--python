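"""Synthetic multi-class expression data with planted ground truth.

The generator emulates the statistical structure of a small paired
patient-vs-control RNA-seq study of four RNA classes:

* two groups (``A`` patients, ``H`` controls) of ``n_per_group`` samples,
  sample i of A paired with sample i of H;
* log-normal expression: per-feature baseline log2 means drawn from
  N(baseline_log2_mean, baseline_log2_sd) and i.i.d. per-sample noise of
  sd ``noise_log2_sd`` on the log2 scale;
* planted DE features shifted by +-``effect_log2fc`` in group A only;
* planted ceRNA triplets (sponge lncRNA/circRNA, miRNA, mRNA) coupled
  through a shared per-sample latent Gaussian factor so that the
  sponge-mRNA correlation is ~ +coupling_r and the miRNA enters with the
  opposite sign (~ -coupling_r against both partners).

Everything is deterministic for a fixed seed; companion generators for
target maps, annotations and qPCR plates draw from independent streams
spawned from the same seed so each artifact is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError
from .matrix import GROUP_A, GROUP_H, RNA_CLASSES, ExpressionMatrix

DEFAULT_FEATURES = {"mRNA": 400, "lncRNA": 300, "circRNA": 150, "miRNA": 100}

_ID_PATTERNS = {
    "mRNA": "ENST{:08d}",
    "lncRNA": "MERGE.{}.1",
    "circRNA": "circR_{:04d}",
    "miRNA": "miR-{:04d}",
}

ENRICHED_TERM_ID = "TERM_ENRICHED"


class PlantedTriplet(NamedTuple):
    sponge: str
    sponge_class: str
    mirna: str
    mrna: str


@dataclass
class SimulationConfig:
    """Study-design parameters of the generator.

    Defaults reflect the emulated design: 3 paired samples per group,
    planted effects of |log2FC| = 3 on 10% of features, log2-scale noise
    sd 0.25, five planted triplets coupled at r = 0.9.
    """

    n_per_group: int = 3
    features_per_class: dict = field(default_factory=lambda: dict(DEFAULT_FEATURES))
    de_fraction: float = 0.1
    effect_log2fc: float = 3.0
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.5
    noise_log2_sd: float = 0.25
    n_triplets: int = 5
    coupling_r: float = 0.9
    decoy_edge_fraction: float = 0.05
    n_terms: int = 20
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise DesignError("n_per_group must be >= 2")
        if not 0 <= self.de_fraction <= 1 or not 0 <= self.decoy_edge_fraction <= 1:
            raise ValidationError("fractions must lie in [0, 1]")
        if not 0 < self.coupling_r <= 1:
            raise ValidationError("coupling_r must lie in (0, 1]")
        if self.effect_log2fc < 0 or self.noise_log2_sd < 0 or self.baseline_log2_sd <= 0:
            raise ValidationError("scale parameters must be nonnegative")
        if self.n_triplets < 0 or self.n_terms < 0:
            raise ValidationError("counts must be >= 0")
        unknown = set(self.features_per_class) - set(RNA_CLASSES)
        if unknown:
            raise ValidationError(f"unknown RNA classes: {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Planted labels emitted by the simulator for recovery tests."""

    de_labels: dict  # class -> {feature -> up|down|null}
    triplets: list[PlantedTriplet]
    enriched_term: str | None = None

    def de_features(self, rna_class: str, direction: str | None = None) -> list[str]:
        labels = self.de_labels[rna_class]
        if direction is None:
            return [f for f, d in labels.items() if d != "null"]
        return [f for f, d in labels.items() if d == direction]

    def null_features(self, rna_class: str) -> list[str]:
        return [f for f, d in self.de_labels[rna_class].items() if d == "null"]


def _sample_frame(n_per_group: int) -> pd.DataFrame:
    names = [f"A{i + 1}" for i in range(n_per_group)] + [f"H{i + 1}" for i in range(n_per_group)]
    return pd.DataFrame(
        {
            "group": [GROUP_A] * n_per_group + [GROUP_H] * n_per_group,
            "pair": [f"P{i + 1}" for i in range(n_per_group)] * 2,
        },
        index=pd.Index(names, name="sample"),
    )


def simulate_expression(config: SimulationConfig) -> tuple[dict, GroundTruth]:
    """Generate one expression matrix per RNA class plus ground truth."""
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_per_group
    samples = _sample_frame(n)
    is_a = np.array([True] * n + [False] * n)

    features = {
        cls: [_ID_PATTERNS[cls].format(i + 1) for i in range(config.features_per_class.get(cls, 0))]
        for cls in RNA_CLASSES
    }

    # plant DE labels: a de_fraction slice per class, split evenly up/down
    de_labels: dict[str, dict[str, str]] = {}
    for cls in RNA_CLASSES:
        ids = features[cls]
        labels = {f: "null" for f in ids}
        n_de = int(round(config.de_fraction * len(ids)))
        chosen = rng.choice(len(ids), size=n_de, replace=False) if n_de else np.array([], int)
        for j, idx in enumerate(sorted(chosen)):
            labels[ids[idx]] = "up" if j % 2 == 0 else "down"
        de_labels[cls] = labels

    triplets = _plant_triplets(config, de_labels)
    truth = GroundTruth(de_labels=de_labels, triplets=triplets)

    # Latent factor per triplet, shared across its three members. The
    # member's per-sample noise is decomposed into a shared part of
    # variance coupling_r * sigma^2 and an independent remainder, so the
    # marginal noise sd stays exactly noise_log2_sd while the noise
    # correlation between members equals +-coupling_r.
    latents = rng.standard_normal((len(triplets), 2 * n))
    sigma = config.noise_log2_sd
    shared_sd = sigma * np.sqrt(config.coupling_r)
    resid_sd = sigma * np.sqrt(1.0 - config.coupling_r)
    coupling: dict[str, tuple[int, float]] = {}
    for t_idx, trip in enumerate(triplets):
        coupling[trip.sponge] = (t_idx, +shared_sd)
        coupling[trip.mrna] = (t_idx, +shared_sd)
        coupling[trip.mirna] = (t_idx, -shared_sd)

    matrices = {}
    for cls in RNA_CLASSES:
        ids = features[cls]
        base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=len(ids))
        white = rng.standard_normal((len(ids), 2 * n))
        log2 = np.empty((len(ids), 2 * n))
        for i, f in enumerate(ids):
            if f in coupling:
                t_idx, s = coupling[f]
                noise_row = s * latents[t_idx] + resid_sd * white[i]
            else:
                noise_row = sigma * white[i]
            log2[i] = base[i] + noise_row
            label = de_labels[cls][f]
            if label == "up":
                log2[i, is_a] += config.effect_log2fc
            elif label == "down":
                log2[i, is_a] -= config.effect_log2fc
        values = pd.DataFrame(2.0 ** log2, index=pd.Index(ids, name="feature"),
                              columns=samples.index)
        matrices[cls] = ExpressionMatrix(values=values, rna_class=cls, samples=samples)
    return matrices, truth


def _plant_triplets(config: SimulationConfig, de_labels: dict) -> list[PlantedTriplet]:
    if config.n_triplets == 0:
        return []
    lnc_up = [f for f, d in de_labels["lncRNA"].items() if d == "up"]
    circ_up = [f for f, d in de_labels["circRNA"].items() if d == "up"]
    mrna_up = [f for f, d in de_labels["mRNA"].items() if d == "up"]
    mirna_down = [f for f, d in de_labels["miRNA"].items() if d == "down"]

    sponges: list[tuple[str, str]] = []
    li = ci = 0
    for k in range(config.n_triplets):
        if (k % 2 == 0 and li < len(lnc_up)) or ci >= len(circ_up):
            if li >= len(lnc_up):
                break
            sponges.append((lnc_up[li], "lncRNA"))
            li += 1
        else:
            sponges.append((circ_up[ci], "circRNA"))
            ci += 1
    if len(sponges) < config.n_triplets or len(mrna_up) < config.n_triplets \
            or len(mirna_down) < config.n_triplets:
        raise DesignError(
            "not enough planted DE features to host n_triplets; "
            "raise de_fraction or features_per_class"
        )
    return [
        PlantedTriplet(sponge=s, sponge_class=cls, mirna=mirna_down[k], mrna=mrna_up[k])
        for k, (s, cls) in enumerate(sponges)
    ]


def simulate_target_map(config: SimulationConfig, truth: GroundTruth):
    """miRNA->target edges: planted-triplet edges plus Bernoulli decoys.

    Decoy edges connect null miRNAs to null mRNA/lncRNA/circRNA features,
    each drawn independently with probability ``decoy_edge_fraction``.
    """
    from .cerna import TargetMap  # local import to avoid a cycle at module load

    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for trip in truth.triplets:
        rows.append((trip.mirna, trip.sponge, trip.sponge_class))
        rows.append((trip.mirna, trip.mrna, "mRNA"))

    null_mirnas = truth.null_features("miRNA")
    null_targets = [
        (f, cls)
        for cls in ("mRNA", "lncRNA", "circRNA")
        for f in truth.null_features(cls)
    ]
    if config.decoy_edge_fraction > 0 and null_mirnas and null_targets:
        hits = rng.random((len(null_mirnas), len(null_targets))) < config.decoy_edge_fraction
        for i, j in zip(*np.nonzero(hits)):
            target, cls = null_targets[j]
            rows.append((null_mirnas[i], target, cls))

    edges = pd.DataFrame(rows, columns=["mirna", "target", "target_class"]).drop_duplicates()
    return TargetMap(edges=edges.reset_index(drop=True))


def simulate_annotation(config: SimulationConfig, truth: GroundTruth):
    """Random gene sets over the mRNA universe plus one DE-enriched term.

    The enriched term draws >= 80% of its members from planted DE mRNAs;
    its id is recorded on ``truth.enriched_term``.
    """
    from .enrichment import CATEGORIES, GeneSet, GeneSetCollection

    rng = np.random.default_rng([config.seed, 2])
    universe = list(truth.de_labels["mRNA"].keys())
    de_mrnas = truth.de_features("mRNA")
    null_mrnas = truth.null_features("mRNA")
    if not de_mrnas:
        raise DesignError("enriched term requires planted DE mRNAs (de_fraction > 0)")

    sets = []
    n_de = min(8, len(de_mrnas))
    n_null = min(n_de // 4, len(null_mrnas))
    members = list(rng.choice(de_mrnas, size=n_de, replace=False))
    members += list(rng.choice(null_mrnas, size=n_null, replace=False))
    sets.append(GeneSet(ENRICHED_TERM_ID, "planted enriched set", "pathway",
                        frozenset(members)))
    truth.enriched_term = ENRICHED_TERM_ID

    for i in range(config.n_terms):
        size = int(rng.integers(10, min(41, len(universe) + 1)))
        genes = frozenset(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"TERM_{i + 1:04d}", f"random set {i + 1}",
                            CATEGORIES[i % len(CATEGORIES)], genes))
    return GeneSetCollection(sets=sets)


def simulate_qpcr(config: SimulationConfig, truth: GroundTruth,
                  genes=None, n_replicates: int = 2) -> pd.DataFrame:
    """Ct plate for selected ncRNAs plus the ACTB reference gene.

    Ct decreases one cycle per log2 unit of expression: a feature planted
    up by ``effect_log2fc`` reads ``effect_log2fc`` cycles earlier in
    group A, so the group difference in dCt equals -log2FC. Replicate
    noise has sd ``noise_log2_sd`` cycles.
    """
    rng = np.random.default_rng([config.seed, 3])
    if genes is None:
        genes = ([t.sponge for t in truth.triplets]
                 or truth.de_features("lncRNA") + truth.de_features("circRNA"))[:5]

    labels = {}
    for cls in ("lncRNA", "circRNA", "mRNA", "miRNA"):
        labels.update(truth.de_labels[cls])

    samples = _sample_frame(config.n_per_group)
    rows = []
    for gene in list(genes) + ["ACTB"]:
        if gene == "ACTB":
            base, lfc = 18.0, 0.0
        else:
            if gene not in labels:
                raise ValidationError(f"unknown gene {gene!r} for qPCR simulation")
            base = float(rng.uniform(22, 28))
            lfc = {"up": config.effect_log2fc, "down": -config.effect_log2fc,
                   "null": 0.0}[labels[gene]]
        for sample, meta in samples.iterrows():
            shift = -lfc if meta["group"] == GROUP_A else 0.0
            for rep in range(1, n_replicates + 1):
                ct = base + shift + rng.normal(0.0, config.noise_log2_sd)
                rows.append((sample, meta["group"], gene, rep, ct))
    return pd.DataFrame(rows, columns=["sample", "group", "gene", "replicate", "ct"])
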