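"""Readers and writers for the on-disk tabular formats.

All formats are UTF-8 TSV with explicit headers ('.' decimal point);
reads are gzip-transparent.  Square similarity tables carry identifiers
in the first row and column; the frequency table is a triplet file
(drug_id, se_id, class); term DAGs are an edge list plus a side-effect →
term mapping; profile tables have an id column followed by numeric
columns.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .config import RunConfig
from .pipeline import METRIC_NAMES
from .similarity import FrequencyMatrix, SimilarityMatrix, TermDAG, ValidationError


def _open(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# frequency triplets
# ---------------------------------------------------------------------------


def read_frequency_table(path, drug_ids=None, se_ids=None) -> FrequencyMatrix:
    """Triplet TSV (drug_id, se_id, class) → FrequencyMatrix.

    Entity orderings default to first appearance; pass explicit id lists
    to fix them.  Conflicting duplicate rows are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"drug_id": str, "se_id": str})
    required = {"drug_id", "se_id", "class"}
    if set(df.columns) < required:
        raise ValidationError(f"{path}: expected columns {sorted(required)}")
    bad = df[~df["class"].isin([1, 2, 3, 4, 5])]
    if len(bad):
        raise ValidationError(
            f"{path}: invalid class at line {bad.index[0] + 2}"  # 1-based + header
        )
    dup = df.groupby(["drug_id", "se_id"])["class"].nunique()
    if (dup > 1).any():
        pair = dup[dup > 1].index[0]
        raise ValidationError(f"{path}: conflicting classes for pair {pair}")
    df = df.drop_duplicates(["drug_id", "se_id"])
    if drug_ids is None:
        drug_ids = list(dict.fromkeys(df["drug_id"]))
    if se_ids is None:
        se_ids = list(dict.fromkeys(df["se_id"]))
    di = {d: i for i, d in enumerate(drug_ids)}
    si = {s: i for i, s in enumerate(se_ids)}
    values = np.zeros((len(drug_ids), len(se_ids)), dtype=int)
    for d, s, c in zip(df["drug_id"], df["se_id"], df["class"]):
        values[di[d], si[s]] = int(c)
    return FrequencyMatrix(values, drug_ids, se_ids)


def write_frequency_table(dsa: FrequencyMatrix, path) -> None:
    pairs = dsa.known_pairs
    df = pd.DataFrame(
        {
            "drug_id": [dsa.drug_ids[i] for i, _ in pairs],
            "se_id": [dsa.se_ids[j] for _, j in pairs],
            "class": dsa.values[pairs[:, 0], pairs[:, 1]],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# square similarity tables
# ---------------------------------------------------------------------------


def read_similarity_table(path, expected_name: str) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row ids differ from column ids")
    values = df.to_numpy(dtype=float)
    if np.abs(values - values.T).max(initial=0.0) > 1e-6:
        raise ValidationError(f"{path}: matrix asymmetric beyond 1e-6")
    values = (values + values.T) / 2.0
    return SimilarityMatrix(values, list(df.index), expected_name)


def write_similarity_table(matrix: SimilarityMatrix, path) -> None:
    pd.DataFrame(matrix.values, index=matrix.ids, columns=matrix.ids).to_csv(
        path, sep="\t", float_format="%.12g"
    )


# ---------------------------------------------------------------------------
# profile tables (fingerprints, embeddings, incidence matrices)
# ---------------------------------------------------------------------------


def read_profile_table(path) -> tuple:
    """TSV with an ``id`` first column; returns (ids, float array)."""
    df = pd.read_csv(path, sep="\t")
    ids = list(df.iloc[:, 0].astype(str))
    return ids, df.iloc[:, 1:].to_numpy(dtype=float)


def write_profile_table(ids, values: np.ndarray, path, prefix: str = "c") -> None:
    values = np.asarray(values)
    df = pd.DataFrame(values, columns=[f"{prefix}{i}" for i in range(values.shape[1])])
    df.insert(0, "id", list(ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# term DAGs
# ---------------------------------------------------------------------------


def read_term_dags(edges_path, mapping_path) -> dict:
    """Global (child, parent) edge list + per-side-effect term mapping.

    Each side effect's DAG is the ancestor closure of its term within
    the global edge list.
    """
    edges = pd.read_csv(edges_path, sep="\t", dtype=str)
    mapping = pd.read_csv(mapping_path, sep="\t", dtype=str)
    parent_of: dict = {}
    for row in edges.itertuples(index=False):
        parent_of.setdefault(row.child, []).append(row.parent)
    dags = {}
    for row in mapping.itertuples(index=False):
        term = row.term
        closure, stack = [], [term]
        seen = set()
        while stack:
            node = stack.pop()
            for parent in parent_of.get(node, []):
                closure.append((node, parent))
                if parent not in seen:
                    seen.add(parent)
                    stack.append(parent)
        dags[row.se_id] = TermDAG(term, closure)
    return dags


def write_term_dags(dags: dict, edges_path, mapping_path) -> None:
    edge_rows, map_rows = [], []
    seen = set()
    for se_id, dag in dags.items():
        map_rows.append({"se_id": se_id, "term": dag.term})
        for child, parent in dag.edges:
            if (child, parent) not in seen:
                seen.add((child, parent))
                edge_rows.append({"child": child, "parent": parent})
    pd.DataFrame(edge_rows, columns=["child", "parent"]).to_csv(
        edges_path, sep="\t", index=False
    )
    pd.DataFrame(map_rows, columns=["se_id", "term"]).to_csv(
        mapping_path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# association score triplets
# ---------------------------------------------------------------------------


def read_association_scores(path) -> dict:
    """TSV (drug_a, drug_b, channel, score) → per-channel pair dicts."""
    df = pd.read_csv(path, sep="\t", dtype={"drug_a": str, "drug_b": str})
    out: dict = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.channel, {})[(row.drug_a, row.drug_b)] = int(row.score)
    return out


def write_association_scores(scores: dict, path) -> None:
    rows = [
        {"drug_a": a, "drug_b": b, "channel": channel, "score": s}
        for channel, pairs in scores.items()
        for (a, b), s in pairs.items()
    ]
    pd.DataFrame(rows, columns=["drug_a", "drug_b", "channel", "score"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# reports and manifests
# ---------------------------------------------------------------------------


def write_report(report: dict, scores: np.ndarray, pairs, ids, path_prefix,
                 fold: int = 0, seed: int = 0, config: RunConfig | None = None) -> tuple:
    """JSON metric report + TSV of per-pair five-class scores.

    Returns (report path, scores path).  The JSON carries exactly the
    eight metrics plus fold, seed and the config hash.
    """
    path_prefix = Path(path_prefix)
    payload = {name: report[name] for name in METRIC_NAMES}
    payload.update(
        fold=fold,
        seed=seed,
        config_hash=config.hash() if config is not None else None,
    )
    report_path = path_prefix.with_suffix(".json")
    with open(report_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
    drug_ids, se_ids = ids
    df = pd.DataFrame(np.asarray(scores), columns=[f"class_{c}" for c in range(1, 6)])
    df.insert(0, "se_id", [se_ids[j] for _, j in pairs])
    df.insert(0, "drug_id", [drug_ids[i] for i, _ in pairs])
    scores_path = path_prefix.with_suffix(".scores.tsv")
    df.to_csv(scores_path, sep="\t", index=False, float_format="%.8g")
    return report_path, scores_path


def write_manifest(path, config: RunConfig, input_paths: dict) -> None:
    """Reproducibility manifest: full config, seed and input file hashes."""
    import hashlib

    hashes = {}
    for name, p in input_paths.items():
        h = hashlib.sha256()
        with open(p, "rb") as fh:
            h.update(fh.read())
        hashes[name] = h.hexdigest()[:16]
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "inputs": hashes,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
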