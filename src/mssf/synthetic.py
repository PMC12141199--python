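"""Seeded generators for every raw input the pipeline consumes.

The generator plants latent clusters on drugs and side effects: a
(drug cluster, side-effect cluster) table assigns each cluster pair a
base frequency class in 1..5, a ``density`` fraction of pairs is
revealed, and each revealed class is resampled uniformly with
probability ``noise_rate``.  All raw feature sources are drawn so that
same-cluster entities look alike — shared fingerprint cores, shared
targets and pathways, nearby embeddings, shared DAG ancestors, and
chemical-association scores that rise with cluster agreement — so every
similarity builder produces matrices with recoverable class signal.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import (
    ASSOCIATION_CHANNELS,
    FrequencyMatrix,
    SimilarityBank,
    TermDAG,
    assemble_bank,
)


@dataclass
class FixtureSpec:
    n_drugs: int = 40
    n_side_effects: int = 50
    n_clusters_drug: int = 4
    n_clusters_se: int = 5
    density: float = 0.3
    noise_rate: float = 0.1
    fingerprint_bits: int = 64
    embed_dim_drug: int = 100
    embed_dim_se: int = 300
    n_pathways: int = 20
    n_enzymes: int = 30
    n_targets: int = 25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if not 0 <= self.noise_rate < 1:
            raise ValueError("noise_rate must be in [0, 1)")
        if self.n_clusters_drug > self.n_drugs or self.n_clusters_se > self.n_side_effects:
            raise ValueError("cluster counts cannot exceed entity counts")
        for name in ("n_drugs", "n_side_effects", "n_clusters_drug", "n_clusters_se",
                     "fingerprint_bits", "n_pathways", "n_enzymes", "n_targets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class RawInputs:
    """Raw feature sources for all 15 similarity builders."""

    association_scores: dict      # channel -> {(drug_id, drug_id): int score}
    fingerprints: np.ndarray      # (n, bits) binary
    target_profiles: np.ndarray   # (n, n_targets) binary
    drug_embeddings: np.ndarray   # (n, embed_dim_drug)
    drug_pathway: np.ndarray      # (n, n_pathways) binary
    pathway_enzyme: np.ndarray    # (n_pathways, n_enzymes) binary
    se_embeddings: np.ndarray     # (m, embed_dim_se)
    se_dags: dict                 # se_id -> TermDAG
    drug_clusters: np.ndarray
    se_clusters: np.ndarray
    base_class: np.ndarray        # (kd, ks) classes in 1..5


def _base_class_table(rng: np.random.Generator, kd: int, ks: int) -> np.ndarray:
    """Cluster-pair base classes: all five classes occur, with mild
    geometric imbalance toward the middle/low classes."""
    n = kd * ks
    weights = 0.75 ** np.arange(5)
    weights /= weights.sum()
    cells = 1 + rng.choice(5, size=n, p=weights)
    if n >= 5:
        for c in np.setdiff1d(np.arange(1, 6), cells):
            # overwrite a cell whose class occurs more than once, so no
            # class is eliminated while the missing one is inserted
            counts = np.bincount(cells, minlength=6)
            donors = np.flatnonzero(counts[cells] > 1)
            pos = donors[rng.integers(len(donors))] if len(donors) else rng.integers(n)
            cells[pos] = c
    return cells.reshape(kd, ks)


def generate(spec: FixtureSpec):
    """Build (FrequencyMatrix, RawInputs) with planted class structure."""
    rng = np.random.default_rng(spec.seed)
    n, m = spec.n_drugs, spec.n_side_effects
    drug_ids = [f"D{i:03d}" for i in range(n)]
    se_ids = [f"S{j:03d}" for j in range(m)]

    # latent clusters (round-robin keeps cluster sizes balanced)
    drug_clusters = rng.permutation(np.arange(n) % spec.n_clusters_drug)
    se_clusters = rng.permutation(np.arange(m) % spec.n_clusters_se)
    base = _base_class_table(rng, spec.n_clusters_drug, spec.n_clusters_se)

    # supervision: reveal ⌊density·n·m⌋ pairs, flip with prob noise_rate
    n_known = int(spec.density * n * m)
    flat = rng.choice(n * m, size=n_known, replace=False)
    values = np.zeros((n, m), dtype=int)
    di, sj = flat // m, flat % m
    classes = base[drug_clusters[di], se_clusters[sj]].copy()
    flip = rng.random(n_known) < spec.noise_rate
    classes[flip] = 1 + rng.integers(0, 5, size=int(flip.sum()))
    values[di, sj] = classes
    dsa = FrequencyMatrix(values, drug_ids, se_ids)

    # chemical-association channels: strong scores within a cluster,
    # occasional weak scores across clusters
    association_scores = {}
    iu, ju = np.triu_indices(n, k=1)
    same = drug_clusters[iu] == drug_clusters[ju]
    for channel in ASSOCIATION_CHANNELS:
        scores = {}
        high = rng.integers(600, 1001, size=len(iu))
        low = rng.integers(1, 301, size=len(iu))
        keep_high = rng.random(len(iu)) < 0.8
        keep_low = rng.random(len(iu)) < 0.15
        for idx in range(len(iu)):
            a, b = drug_ids[iu[idx]], drug_ids[ju[idx]]
            if same[idx] and keep_high[idx]:
                scores[(a, b)] = int(high[idx])
            elif not same[idx] and keep_low[idx]:
                scores[(a, b)] = int(low[idx])
        association_scores[channel] = scores

    # fingerprints: a cluster core of set bits plus per-drug noise bits
    bits = spec.fingerprint_bits
    core_size = max(2, bits // (2 * spec.n_clusters_drug))
    cores = [
        rng.choice(bits, size=core_size, replace=False)
        for _ in range(spec.n_clusters_drug)
    ]
    fingerprints = np.zeros((n, bits), dtype=int)
    for i in range(n):
        fingerprints[i, cores[drug_clusters[i]]] = 1
        extra = rng.choice(bits, size=max(1, core_size // 3), replace=False)
        fingerprints[i, extra] = 1

    # drug–target incidence: cluster-specific targets plus noise
    targets_per = max(1, spec.n_targets // spec.n_clusters_drug)
    target_profiles = np.zeros((n, spec.n_targets), dtype=int)
    for i in range(n):
        c = drug_clusters[i]
        block = np.arange(c * targets_per, min((c + 1) * targets_per, spec.n_targets))
        target_profiles[i, block] = 1
        if rng.random() < 0.3:
            target_profiles[i, rng.integers(spec.n_targets)] = 1

    # substructure embeddings: cluster centroid + isotropic noise
    centroids = rng.standard_normal((spec.n_clusters_drug, spec.embed_dim_drug))
    drug_embeddings = (
        centroids[drug_clusters] + 0.3 * rng.standard_normal((n, spec.embed_dim_drug))
    )

    # pathways: each cluster owns a pathway block; enzymes random per pathway
    paths_per = max(1, spec.n_pathways // spec.n_clusters_drug)
    drug_pathway = np.zeros((n, spec.n_pathways), dtype=int)
    for i in range(n):
        c = drug_clusters[i]
        block = np.arange(c * paths_per, min((c + 1) * paths_per, spec.n_pathways))
        drug_pathway[i, block] = (rng.random(len(block)) < 0.8).astype(int)
        if not drug_pathway[i].any():
            drug_pathway[i, block[0] if len(block) else 0] = 1
    pathway_enzyme = (rng.random((spec.n_pathways, spec.n_enzymes)) < 0.25).astype(int)
    empty = ~pathway_enzyme.any(axis=1)
    pathway_enzyme[empty, 0] = 1

    # side-effect word embeddings
    se_centroids = rng.standard_normal((spec.n_clusters_se, spec.embed_dim_se))
    se_embeddings = (
        se_centroids[se_clusters] + 0.3 * rng.standard_normal((m, spec.embed_dim_se))
    )

    # term DAGs: term -> cluster ancestor -> root; same-cluster terms
    # share ancestors, so Wang similarity separates the clusters
    se_dags = {}
    for j, sid in enumerate(se_ids):
        term = f"T_{sid}"
        cluster_node = f"C{se_clusters[j]}"
        edges = [(term, cluster_node), (cluster_node, "ROOT")]
        if rng.random() < 0.2:  # occasional secondary parent
            other = f"C{rng.integers(spec.n_clusters_se)}"
            if other != cluster_node:
                edges.append((term, other))
                edges.append((other, "ROOT"))
        se_dags[sid] = TermDAG(term, edges)

    raw = RawInputs(
        association_scores=association_scores,
        fingerprints=fingerprints,
        target_profiles=target_profiles,
        drug_embeddings=drug_embeddings,
        drug_pathway=drug_pathway,
        pathway_enzyme=pathway_enzyme,
        se_embeddings=se_embeddings,
        se_dags=se_dags,
        drug_clusters=drug_clusters,
        se_clusters=se_clusters,
        base_class=base,
    )
    return dsa, raw


def build_bank(dsa: FrequencyMatrix, raw: RawInputs, mask: bool = False,
               decay: float = 0.5) -> SimilarityBank:
    """Assemble the full similarity bank from generated raw inputs."""
    return assemble_bank(
        dsa,
        raw.association_scores,
        raw.fingerprints,
        raw.target_profiles,
        raw.drug_embeddings,
        raw.drug_pathway,
        raw.pathway_enzyme,
        raw.se_embeddings,
        raw.se_dags,
        mask=mask,
        decay=decay,
    )


def worked_example():
    """A tiny fixed 4-drug × 3-side-effect instance.

    Every raw input is hard-coded so the 15 similarity matrices can be
    enumerated by hand; the test suite carries the hand-computed values.
    """
    drug_ids = ["D1", "D2", "D3", "D4"]
    se_ids = ["S1", "S2", "S3"]

    dsa = FrequencyMatrix(
        np.array([[1, 3, 0], [2, 0, 5], [0, 4, 0], [5, 3, 0]]), drug_ids, se_ids
    )

    association_scores = {
        "similarity": {("D1", "D2"): 1000, ("D1", "D3"): 500},
        "experimental": {("D2", "D3"): 250},
        "database": {("D1", "D4"): 800},
        "text": {("D2", "D4"): 100},
        "combined": {("D1", "D2"): 900, ("D3", "D4"): 400},
    }
    fingerprints = np.array(
        [
            [1, 1, 1, 0, 0, 0, 0, 0],
            [0, 1, 1, 1, 0, 0, 0, 0],
            [0, 0, 0, 0, 1, 1, 1, 0],
            [1, 1, 1, 0, 0, 0, 0, 0],
        ]
    )
    target_profiles = np.array(
        [[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 1], [0, 0, 0, 0]]
    )
    drug_embeddings = np.array(
        [[1.0, 0.0, 0.0], [1.0, 1.0, 0.0], [0.0, 0.0, 1.0], [-1.0, 0.0, 0.0]]
    )
    drug_pathway = np.array([[1, 1], [0, 1], [1, 0], [0, 0]])
    pathway_enzyme = np.array([[1, 0], [1, 1]])
    se_embeddings = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
    # S1 = term a under root R; S2 = R itself; S3 = term b under R
    se_dags = {
        "S1": TermDAG("a", [("a", "R")]),
        "S2": TermDAG("R", []),
        "S3": TermDAG("b", [("b", "R")]),
    }
    raw = RawInputs(
        association_scores=association_scores,
        fingerprints=fingerprints,
        target_profiles=target_profiles,
        drug_embeddings=drug_embeddings,
        drug_pathway=drug_pathway,
        pathway_enzyme=pathway_enzyme,
        se_embeddings=se_embeddings,
        se_dags=se_dags,
        drug_clusters=np.array([0, 0, 1, 0]),
        se_clusters=np.array([0, 1, 0]),
        base_class=np.array([[1, 3], [4, 5]]),
    )
    return dsa, raw
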