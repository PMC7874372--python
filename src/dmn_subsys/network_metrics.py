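"""Weighted-network summaries on per-subject connectivity matrices.

The central statistic is the modularity index Q of a weighted, undirected
connectivity matrix evaluated against a fixed a-priori partition (no
community detection).  Fisher-z matrices can carry negative weights; two
conventions are implemented:

``positive_only``
    Negative weights are set to zero and the classic weighted Newman
    modularity is computed on the positive part:
    Q = (1/2m+) Σ_ij [w+_ij − k+_i k+_j / 2m+] δ(c_i, c_j).

``signed_asymmetric`` (default)
    Positive and negative parts are scored separately and combined
    asymmetrically, Q = Q+ − m−/(m+ + m−) · Q−, so that negative
    within-module weight is penalised but cannot dominate.

Alongside Q, the module-level "summed connection strengths" are reported:
the sum of edge weights over unordered node pairs within each module and
over all pairs spanning two modules.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rois import ModulePartition

MODULARITY_MODES = ("signed_asymmetric", "positive_only")


def _validate_matrix(z: np.ndarray, n_nodes: int) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if z.shape != (n_nodes, n_nodes):
        raise ValueError(f"expected a {n_nodes}x{n_nodes} matrix, got {z.shape}")
    if not np.all(np.isfinite(z)):
        raise ValueError("connectivity matrix contains non-finite values")
    if not np.allclose(z, z.T, atol=1e-12, rtol=0.0):
        raise ValueError("connectivity matrix is not symmetric")
    z = z.copy()
    np.fill_diagonal(z, 0.0)
    return z


def _q_one_sign(w: np.ndarray, same_module: np.ndarray) -> tuple[float, float]:
    """Newman Q for a non-negative matrix; returns (Q, total weight m)."""
    k = w.sum(axis=1)
    two_m = k.sum()
    if two_m == 0.0:
        return 0.0, 0.0
    null = np.outer(k, k) / two_m
    q = ((w - null) * same_module).sum() / two_m
    return float(q), float(two_m / 2.0)


def modularity_index(
    z: np.ndarray,
    partition: ModulePartition,
    labels: list[str],
    mode: str = "signed_asymmetric",
) -> float:
    """Modularity index Q of a weighted undirected matrix for a fixed partition.

    Parameters
    ----------
    z :
        Symmetric connectivity matrix (diagonal is forced to 0).
    partition :
        Node-label → module assignment covering every entry of `labels`.
    labels :
        Node labels in matrix row/column order.
    mode :
        ``"signed_asymmetric"`` or ``"positive_only"`` (see module docstring).

    Returns
    -------
    float
        Q in [−1, 1]; 0 when the relevant total weight is zero.
    """
    if mode not in MODULARITY_MODES:
        raise ValueError(f"unknown modularity mode {mode!r}")
    w = _validate_matrix(z, len(labels))
    ci = partition.indices(labels)
    same = (ci[:, None] == ci[None, :]).astype(float)

    w_pos = np.where(w > 0, w, 0.0)
    q_pos, m_pos = _q_one_sign(w_pos, same)
    if mode == "positive_only":
        return q_pos
    w_neg = np.where(w < 0, -w, 0.0)
    q_neg, m_neg = _q_one_sign(w_neg, same)
    if m_pos + m_neg == 0.0:
        return 0.0
    return q_pos - m_neg / (m_pos + m_neg) * q_neg


def module_strengths(
    z: np.ndarray, partition: ModulePartition, labels: list[str]
) -> tuple[dict[str, float], float]:
    """Summed connection strength within each module and between modules.

    Sums run over unordered node pairs (each edge counted once).  With the
    default 5/4/2 partition of 11 nodes the pair counts are 10 + 6 + 1
    within and 38 between, totalling C(11, 2) = 55.

    Returns
    -------
    (within, between) :
        ``within`` maps module label → summed weight over pairs inside the
        module; ``between`` is the summed weight over pairs spanning two
        different modules.
    """
    w = _validate_matrix(z, len(labels))
    ci = partition.indices(labels)
    iu, ju = np.triu_indices(len(labels), k=1)
    vals = w[iu, ju]
    same = ci[iu] == ci[ju]
    within = {
        m: float(vals[same & (ci[iu] == k)].sum())
        for k, m in enumerate(partition.modules)
    }
    between = float(vals[~same].sum())
    return within, between


def node_strength(z: np.ndarray, labels: list[str]) -> pd.Series:
    """Per-node strength: sum of incident edge weights."""
    w = _validate_matrix(z, len(labels))
    return pd.Series(w.sum(axis=1), index=labels, name="strength")


@dataclass(frozen=True)
class NetworkSummary:
    """Per-subject network summary over the fixed partition."""

    subject_id: str
    q: float
    within_strength: dict[str, float]
    between_strength: float
    node_strength: pd.Series
    total_weight: float
    mode: str

    def as_row(self) -> dict[str, float | str]:
        row: dict[str, float | str] = {"subject_id": self.subject_id, "Q": self.q}
        for m, v in self.within_strength.items():
            row[f"within_{m}"] = v
        row["between"] = self.between_strength
        return row


def summarize_network(
    subject_id: str,
    z: np.ndarray,
    partition: ModulePartition,
    labels: list[str],
    mode: str = "signed_asymmetric",
) -> NetworkSummary:
    """Compute Q, module strengths and node strengths for one subject."""
    w = _validate_matrix(z, len(labels))
    within, between = module_strengths(w, partition, labels)
    return NetworkSummary(
        subject_id=subject_id,
        q=modularity_index(w, partition, labels, mode=mode),
        within_strength=within,
        between_strength=between,
        node_strength=node_strength(w, labels),
        total_weight=float(w.sum() / 2.0),
        mode=mode,
    )


def summaries_table(summaries: list[NetworkSummary]) -> pd.DataFrame:
    """Stack per-subject summaries into one table (one row per subject)."""
    return pd.DataFrame([s.as_row() for s in summaries])
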