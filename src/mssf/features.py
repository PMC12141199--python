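"""Per-pair feature assembly from the similarity bank.

For drug *i* and side effect *j* the raw features are the *i*-th rows of
the P drug similarity matrices and the *j*-th rows of the Q side-effect
matrices (P = 11, Q = 4 unmasked; 9 and 2 masked).  Three combinations
feed the three extractor branches:

* ``concat`` — all vectors concatenated in bank order,
  length P·#drugs + Q·#side-effects;
* ``add``    — elementwise sum of the drug vectors followed by the sum
  of the side-effect vectors, length #drugs + #side-effects;
* ``maps``   — P·Q rank-1 interaction maps, the outer products of
  per-source linear projections of the raw vectors into width h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import SimilarityBank


@dataclass
class EntityFeatures:
    """Ordered similarity-row vectors for one drug or side effect."""

    vectors: list  # list of 1-D arrays, in bank order
    entity_id: object

    def stacked(self) -> np.ndarray:
        return np.stack(self.vectors)


@dataclass
class CombinedFeatures:
    concat: np.ndarray
    add: np.ndarray
    maps: np.ndarray  # (P*Q, h, h)


def collect_features(bank: SimilarityBank, drug_index: int, se_index: int):
    """Rows of every bank matrix for one (drug, side effect) pair."""
    drug_ids, se_ids = bank.drug_ids, bank.se_ids
    if not 0 <= drug_index < len(drug_ids):
        raise IndexError(f"drug index {drug_index} out of range")
    if not 0 <= se_index < len(se_ids):
        raise IndexError(f"side-effect index {se_index} out of range")
    drug = EntityFeatures(
        [m.values[drug_index] for m in bank.drug_matrices.values()],
        drug_ids[drug_index],
    )
    se = EntityFeatures(
        [m.values[se_index] for m in bank.se_matrices.values()],
        se_ids[se_index],
    )
    return drug, se


def combine_concat(drug_feats: EntityFeatures, se_feats: EntityFeatures) -> np.ndarray:
    return np.concatenate(drug_feats.vectors + se_feats.vectors)


def combine_add(drug_feats: EntityFeatures, se_feats: EntityFeatures) -> np.ndarray:
    return np.concatenate(
        [drug_feats.stacked().sum(axis=0), se_feats.stacked().sum(axis=0)]
    )


def interaction_maps(
    drug_feats: EntityFeatures,
    se_feats: EntityFeatures,
    drug_proj: np.ndarray,
    se_proj: np.ndarray,
    h: int,
) -> np.ndarray:
    """Outer-product interaction maps from projected representations.

    ``drug_proj`` has shape (P, #drugs, h), ``se_proj`` (Q, #side-effects, h);
    map k (drug-major: k = p·Q + q) is the outer product of projection p of
    the drug vector with projection q of the side-effect vector.  Each map
    has rank ≤ 1 by construction.
    """
    if h <= 0:
        raise ValueError("projection width h must be positive")
    xd = np.einsum("pn,pnh->ph", drug_feats.stacked(), np.asarray(drug_proj))
    xs = np.einsum("qm,qmh->qh", se_feats.stacked(), np.asarray(se_proj))
    maps = xd[:, None, :, None] * xs[None, :, None, :]  # (P, Q, h, h)
    p, q = xd.shape[0], xs.shape[0]
    return maps.reshape(p * q, h, h)


def combine(
    drug_feats: EntityFeatures,
    se_feats: EntityFeatures,
    drug_proj: np.ndarray,
    se_proj: np.ndarray,
    h: int,
) -> CombinedFeatures:
    """All three feature combinations for one pair."""
    return CombinedFeatures(
        concat=combine_concat(drug_feats, se_feats),
        add=combine_add(drug_feats, se_feats),
        maps=interaction_maps(drug_feats, se_feats, drug_proj, se_proj, h),
    )


def assemble_batch(bank: SimilarityBank, pairs: np.ndarray) -> dict:
    """Vectorized raw inputs for a batch of (drug, se) index pairs.

    Returns numpy arrays consumed by the network:
    ``concat`` (B, P·n + Q·m), ``add`` (B, n + m),
    ``drug_raw`` (B, P, n), ``se_raw`` (B, Q, m).
    The learnable interaction-map projections live in the model, so the
    raw per-source vectors are passed through.
    """
    pairs = np.asarray(pairs)
    drug_stack = np.stack([m.values for m in bank.drug_matrices.values()])  # (P, n, n)
    se_stack = np.stack([m.values for m in bank.se_matrices.values()])  # (Q, m, m)
    di, sj = pairs[:, 0], pairs[:, 1]
    drug_raw = drug_stack[:, di, :].transpose(1, 0, 2)  # (B, P, n)
    se_raw = se_stack[:, sj, :].transpose(1, 0, 2)  # (B, Q, m)
    b = len(pairs)
    return {
        "concat": np.concatenate(
            [drug_raw.reshape(b, -1), se_raw.reshape(b, -1)], axis=1
        ),
        "add": np.concatenate(
            [drug_raw.sum(axis=1), se_raw.sum(axis=1)], axis=1
        ),
        "drug_raw": drug_raw,
        "se_raw": se_raw,
    }
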