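"""Construction of the drug and side-effect similarity matrices.

Eleven drug similarities and four side-effect similarities feed the
fusion model:

* five chemical–chemical association channels (``similarity``,
  ``experimental``, ``database``, ``text``, ``combined``), integer scores
  in [1, 1000] rescaled to [0, 1];
* ``structure`` — Tanimoto/Jaccard similarity of binary fingerprints;
* ``target`` — cosine similarity of drug–target incidence vectors;
* ``word`` — cosine similarity of real-valued substructure embeddings;
* ``pathway_enzyme`` — cosine similarity of the rows of the
  (drug × pathway) · (pathway × enzyme) product;
* ``dipf`` / ``dipa`` — cosine similarity of raw / binarized rows
  (drugs) or columns (side effects) of the known frequency-class matrix;
* ``semantic`` — Wang-style decayed-contribution similarity on the
  side-effect term DAGs;
* side-effect ``word`` — cosine similarity of term embeddings.

Every matrix is validated to be symmetric, unit-diagonal and in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

DRUG_MATRIX_NAMES = (
    "stitch_similarity",
    "stitch_experimental",
    "stitch_database",
    "stitch_text",
    "stitch_combined",
    "structure",
    "target",
    "word",
    "pathway_enzyme",
    "dipa",
    "dipf",
)
SE_MATRIX_NAMES = ("semantic", "word", "dipa", "dipf")
#: names removed in cold-start / independent protocols (they derive from
#: known frequencies, unavailable for new drugs)
DSA_DERIVED = ("dipa", "dipf")

ASSOCIATION_CHANNELS = (
    "similarity",
    "experimental",
    "database",
    "text",
    "combined",
)

_SYM_TOL = 1e-9


class ValidationError(ValueError):
    """Raised when an input or a produced matrix violates its contract."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class FrequencyMatrix:
    """Drug × side-effect matrix of frequency classes (0 = unknown, 1–5)."""

    values: np.ndarray
    drug_ids: list
    se_ids: list
    #: a fold-masked training matrix may legitimately lose all entries
    allow_empty: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values)
        self.drug_ids = list(self.drug_ids)
        self.se_ids = list(self.se_ids)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValidationError("frequency matrix must be 2-D")
        if not np.isin(v, [0, 1, 2, 3, 4, 5]).all():
            raise ValidationError("frequency classes must be integers in 0..5")
        if not self.allow_empty and not (v != 0).any():
            raise ValidationError("frequency matrix has no known entries")
        if len(self.drug_ids) != v.shape[0] or len(self.se_ids) != v.shape[1]:
            raise ValidationError("id list lengths do not match matrix shape")
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValidationError("duplicate drug ids")
        if len(set(self.se_ids)) != len(self.se_ids):
            raise ValidationError("duplicate side-effect ids")

    @property
    def known_pairs(self) -> np.ndarray:
        """(n_known, 2) array of (drug index, side-effect index)."""
        return np.argwhere(self.values != 0)

    def mask_pairs(self, pairs) -> "FrequencyMatrix":
        """Return a copy with the given (i, j) entries zeroed (test fold)."""
        v = self.values.copy()
        pairs = np.asarray(pairs)
        if len(pairs):
            v[pairs[:, 0], pairs[:, 1]] = 0
        return FrequencyMatrix(v, self.drug_ids, self.se_ids, allow_empty=True)


@dataclass
class SimilarityMatrix:
    """Validated symmetric similarity matrix with unit diagonal."""

    values: np.ndarray
    ids: list
    name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.ids = list(self.ids)
        self.validate()

    def validate(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError(f"{self.name}: matrix must be square")
        if len(self.ids) != v.shape[0]:
            raise ValidationError(f"{self.name}: id count != matrix size")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValidationError(f"{self.name}: matrix not symmetric")
        if v.min(initial=1.0) < -_SYM_TOL or v.max(initial=0.0) > 1 + _SYM_TOL:
            raise ValidationError(f"{self.name}: entries outside [0, 1]")
        if not np.allclose(np.diag(v), 1.0, atol=_SYM_TOL):
            raise ValidationError(f"{self.name}: diagonal must be 1")


@dataclass
class SimilarityBank:
    """The named collection of drug and side-effect similarity matrices."""

    drug_matrices: dict
    se_matrices: dict
    masked: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        want_drug = [n for n in DRUG_MATRIX_NAMES if not (self.masked and n in DSA_DERIVED)]
        want_se = [n for n in SE_MATRIX_NAMES if not (self.masked and n in DSA_DERIVED)]
        if list(self.drug_matrices) != want_drug:
            raise ValidationError(
                f"drug matrices {list(self.drug_matrices)} != expected {want_drug}"
            )
        if list(self.se_matrices) != want_se:
            raise ValidationError(
                f"side-effect matrices {list(self.se_matrices)} != expected {want_se}"
            )
        for group in (self.drug_matrices, self.se_matrices):
            ids = None
            for m in group.values():
                m.validate()
                if ids is None:
                    ids = m.ids
                elif m.ids != ids:
                    raise ValidationError("matrices in a group must share id ordering")

    @property
    def drug_ids(self) -> list:
        return next(iter(self.drug_matrices.values())).ids

    @property
    def se_ids(self) -> list:
        return next(iter(self.se_matrices.values())).ids

    @property
    def n_drug_matrices(self) -> int:
        return len(self.drug_matrices)

    @property
    def n_se_matrices(self) -> int:
        return len(self.se_matrices)

    def apply_mask(self) -> "SimilarityBank":
        """Drop the DSA-derived matrices (cold-start / independent runs)."""
        if self.masked:
            return self
        return SimilarityBank(
            {k: v for k, v in self.drug_matrices.items() if k not in DSA_DERIVED},
            {k: v for k, v in self.se_matrices.items() if k not in DSA_DERIVED},
            masked=True,
        )


@dataclass
class TermDAG:
    """Ancestor closure of one side-effect term in the term hierarchy."""

    term: str
    edges: list = field(default_factory=list)  # (child, parent) pairs

    def __post_init__(self):
        g = nx.DiGraph()
        g.add_node(self.term)
        g.add_edges_from(self.edges)
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError(f"term DAG of {self.term} contains a cycle")
        if self.term not in g:
            raise ValidationError(f"term {self.term} absent from its own DAG")
        self._graph = g

    @property
    def nodes(self):
        return set(self._graph.nodes)

    @property
    def roots(self):
        return {n for n in self._graph if self._graph.out_degree(n) == 0}

    def s_values(self, decay: float = 0.5) -> dict:
        """Wang-style decayed contribution of every term to ``self.term``.

        S(term) = 1; S(parent) = max over children c of decay * S(c),
        propagated along (child, parent) edges.
        """
        s = {self.term: 1.0}
        for node in nx.topological_sort(self._graph):
            if node not in s:
                continue
            for parent in self._graph.successors(node):
                cand = decay * s[node]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
        return s


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def scale_association_scores(raw: dict, drug_ids: list, channel: str) -> SimilarityMatrix:
    """Rescale integer association scores in [1, 1000] to [0, 1].

    ``raw`` maps (drug_id, drug_id) pairs to integer scores; an absent
    pair has similarity 0 and the diagonal is fixed at 1.
    """
    if channel not in ASSOCIATION_CHANNELS:
        raise ValidationError(f"unknown association channel {channel!r}")
    index = {d: i for i, d in enumerate(drug_ids)}
    n = len(drug_ids)
    m = np.zeros((n, n))
    seen: dict = {}
    for (a, b), score in raw.items():
        if not (1 <= score <= 1000) or int(score) != score:
            raise ValidationError(
                f"association score {score} for pair ({a}, {b}) outside [1, 1000]"
            )
        key = (min(a, b), max(a, b))
        if key in seen and seen[key] != score:
            raise ValidationError(f"conflicting scores for pair {key}")
        seen[key] = score
        i, j = index[a], index[b]
        m[i, j] = m[j, i] = score / 1000.0
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(m, drug_ids, f"stitch_{channel}")


def tanimoto_matrix(fingerprints: np.ndarray, ids: list, name: str = "structure") -> SimilarityMatrix:
    """Jaccard similarity of binary fingerprint bit vectors."""
    fp = np.asarray(fingerprints)
    if not np.isin(fp, [0, 1]).all():
        raise ValidationError("fingerprints must be binary")
    counts = fp.sum(axis=1)
    if (counts == 0).any():
        warnings.warn("all-zero fingerprint: similarity defined as 0", stacklevel=2)
    fp = fp.astype(float)
    inter = fp @ fp.T
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(m, ids, name)


def cosine_similarity_matrix(profiles: np.ndarray, ids: list, name: str) -> SimilarityMatrix:
    """Cosine similarity of real-valued profile rows, clipped to [0, 1].

    A zero profile has similarity 0 to everything (diagonal stays 1);
    negative cosines (possible for signed embeddings) are clipped to 0.
    """
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2:
        raise ValidationError("profiles must be a 2-D array")
    norms = np.linalg.norm(p, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = p / safe[:, None]
    m = unit @ unit.T
    m[norms == 0, :] = 0.0
    m[:, norms == 0] = 0.0
    m = np.clip(m, 0.0, 1.0)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 1.0)
    return SimilarityMatrix(m, ids, name)


def build_dsa_similarities(dsa: FrequencyMatrix, axis: str, binarize: bool) -> SimilarityMatrix:
    """Frequency-profile similarity (DIPF raw classes / DIPA binarized)."""
    if axis == "drugs":
        profiles, ids = dsa.values, dsa.drug_ids
    elif axis == "side_effects":
        profiles, ids = dsa.values.T, dsa.se_ids
    else:
        raise ValidationError(f"axis must be 'drugs' or 'side_effects', got {axis!r}")
    profiles = profiles.astype(float)
    if binarize:
        profiles = (profiles != 0).astype(float)
    return cosine_similarity_matrix(profiles, ids, "dipa" if binarize else "dipf")


def pathway_enzyme_similarity(
    drug_pathway: np.ndarray, pathway_enzyme: np.ndarray, ids: list
) -> SimilarityMatrix:
    """Cosine similarity of drug–enzyme profiles via the pathway product."""
    dp = np.asarray(drug_pathway, dtype=float)
    pe = np.asarray(pathway_enzyme, dtype=float)
    if not np.isin(dp, [0, 1]).all() or not np.isin(pe, [0, 1]).all():
        raise ValidationError("incidence matrices must be binary")
    if dp.shape[1] != pe.shape[0]:
        raise ValidationError(
            f"inner dimensions disagree: {dp.shape[1]} pathways vs {pe.shape[0]}"
        )
    return cosine_similarity_matrix(dp @ pe, ids, "pathway_enzyme")


def semantic_similarity(dags: dict, ids: list, decay: float = 0.5) -> SimilarityMatrix:
    """Wang-style semantic similarity between side-effect term DAGs.

    sim(x, y) = Σ_{t ∈ T_x ∩ T_y} (S_x(t) + S_y(t)) /
                (Σ_{t ∈ T_x} S_x(t) + Σ_{t ∈ T_y} S_y(t))
    """
    if not 0 < decay <= 1:
        raise ValidationError("decay must be in (0, 1]")
    svals = {sid: dags[sid].s_values(decay) for sid in ids}
    totals = {sid: sum(s.values()) for sid, s in svals.items()}
    n = len(ids)
    m = np.eye(n)
    for i in range(n):
        si = svals[ids[i]]
        for j in range(i + 1, n):
            sj = svals[ids[j]]
            shared = set(si) & set(sj)
            num = sum(si[t] + sj[t] for t in shared)
            den = totals[ids[i]] + totals[ids[j]]
            m[i, j] = m[j, i] = num / den if den > 0 else 0.0
    return SimilarityMatrix(np.clip(m, 0.0, 1.0), ids, "semantic")


def assemble_bank(
    dsa: FrequencyMatrix,
    association_scores: dict,
    fingerprints: np.ndarray,
    target_profiles: np.ndarray,
    drug_embeddings: np.ndarray,
    drug_pathway: np.ndarray,
    pathway_enzyme: np.ndarray,
    se_embeddings: np.ndarray,
    se_dags: dict,
    mask: bool = False,
    precomputed: dict | None = None,
    decay: float = 0.5,
) -> SimilarityBank:
    """Build all 15 similarity matrices (11 drug + 4 side-effect).

    ``precomputed`` may supply ready ``SimilarityMatrix`` objects keyed by
    ``("drug", name)`` / ``("se", name)``, overriding construction.
    ``mask=True`` drops the DSA-derived matrices (9 + 2 remain).
    """
    precomputed = precomputed or {}
    drug_ids, se_ids = dsa.drug_ids, dsa.se_ids

    sources = {
        ("drug", "structure"): lambda: tanimoto_matrix(fingerprints, drug_ids),
        ("drug", "target"): lambda: cosine_similarity_matrix(target_profiles, drug_ids, "target"),
        ("drug", "word"): lambda: cosine_similarity_matrix(drug_embeddings, drug_ids, "word"),
        ("drug", "pathway_enzyme"): lambda: pathway_enzyme_similarity(
            drug_pathway, pathway_enzyme, drug_ids
        ),
        ("drug", "dipa"): lambda: build_dsa_similarities(dsa, "drugs", binarize=True),
        ("drug", "dipf"): lambda: build_dsa_similarities(dsa, "drugs", binarize=False),
        ("se", "semantic"): lambda: semantic_similarity(se_dags, se_ids, decay),
        ("se", "word"): lambda: cosine_similarity_matrix(se_embeddings, se_ids, "word"),
        ("se", "dipa"): lambda: build_dsa_similarities(dsa, "side_effects", binarize=True),
        ("se", "dipf"): lambda: build_dsa_similarities(dsa, "side_effects", binarize=False),
    }
    for channel in ASSOCIATION_CHANNELS:
        key = ("drug", f"stitch_{channel}")
        sources[key] = (
            lambda ch=channel: scale_association_scores(
                association_scores[ch], drug_ids, ch
            )
        )

    missing = []
    drug_matrices: dict = {}
    se_matrices: dict = {}
    for name in DRUG_MATRIX_NAMES:
        key = ("drug", name)
        try:
            drug_matrices[name] = precomputed.get(key) or sources[key]()
        except KeyError:
            missing.append(name)
    for name in SE_MATRIX_NAMES:
        key = ("se", name)
        try:
            se_matrices[name] = precomputed.get(key) or sources[key]()
        except KeyError:
            missing.append(name)
    if missing:
        raise ValidationError(f"missing sources for similarity matrices: {missing}")

    bank = SimilarityBank(drug_matrices, se_matrices, masked=False)
    return bank.apply_mask() if mask else bank


def refit_dsa_similarities(bank: SimilarityBank, dsa_train: FrequencyMatrix) -> SimilarityBank:
    """Recompute DIPA/DIPF from training-only frequency entries.

    Leakage control for pairwise cross-validation: the test fold's
    entries are zeroed in ``dsa_train`` before the frequency-profile
    similarities are rebuilt; the other matrices are untouched.
    """
    if bank.masked:
        raise ValidationError("cannot refit DSA similarities on a masked bank")
    drug = dict(bank.drug_matrices)
    se = dict(bank.se_matrices)
    drug["dipa"] = build_dsa_similarities(dsa_train, "drugs", binarize=True)
    drug["dipf"] = build_dsa_similarities(dsa_train, "drugs", binarize=False)
    se["dipa"] = build_dsa_similarities(dsa_train, "side_effects", binarize=True)
    se["dipf"] = build_dsa_similarities(dsa_train, "side_effects", binarize=False)
    return SimilarityBank(drug, se, masked=False)
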