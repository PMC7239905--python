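"""Removal of tissue/covariate effects by linear projection.

Premultiplies the extended matrix by ``I - Q (Q'Q)^{-1} Q'`` where ``Q`` is
an indicator (or general design) matrix, i.e. residualizes every column on
the group membership.  For one-hot designs this is group-wise demeaning in
O(np); general designs go through an orthogonal (QR) decomposition.  The
dense n x n projector is never formed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .blocks import ExtendedMatrix

__all__ = ["ProjectorDesign", "build_indicator", "apply_projection"]


@dataclass
class ProjectorDesign:
    """Membership design ``Q`` (n x t) with ordered group labels."""

    Q: np.ndarray
    group_labels: list[str]

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2:
            raise ValueError("Q must be 2-D")

    @property
    def is_one_hot(self) -> bool:
        Q = self.Q
        return (np.isin(Q, (0.0, 1.0)).all()
                and np.allclose(Q.sum(axis=1), 1.0))


def build_indicator(labels: Sequence) -> ProjectorDesign:
    """One-hot membership matrix, columns ordered by first appearance."""
    labels = list(labels)
    if not labels:
        raise ValueError("no labels given")
    order: list = []
    for lab in labels:
        if lab not in order:
            order.append(lab)
    idx = {lab: j for j, lab in enumerate(order)}
    Q = np.zeros((len(labels), len(order)))
    Q[np.arange(len(labels)), [idx[lab] for lab in labels]] = 1.0
    return ProjectorDesign(Q, [str(g) for g in order])


def _project_array(X: np.ndarray, design: ProjectorDesign) -> np.ndarray:
    Q = design.Q
    if Q.shape[0] != X.shape[0]:
        raise ValueError("Q and X have different numbers of rows")
    if design.is_one_hot:
        # group-wise demeaning
        out = X.astype(float, copy=True)
        groups = Q.argmax(axis=1)
        for g in range(Q.shape[1]):
            members = groups == g
            if members.any():
                out[members] -= out[members].mean(axis=0)
        return out
    # general design: drop redundant columns, then QR residualization
    rank = np.linalg.matrix_rank(Q)
    if rank < Q.shape[1]:
        # identify a maximal independent subset; report the rest
        R = np.linalg.qr(Q, mode="r")
        dep = np.flatnonzero(np.abs(np.diag(R)) < 1e-10 * max(1.0, np.abs(R).max()))
        labels = [design.group_labels[j] if j < len(design.group_labels) else str(j)
                  for j in dep]
        raise ValueError(f"design is rank deficient; collinear columns: {labels}")
    Qo, _ = np.linalg.qr(Q)
    return X - Qo @ (Qo.T @ X)


def apply_projection(X: ExtendedMatrix | np.ndarray,
                     design: ProjectorDesign):
    """Return ``(I - Q(Q'Q)^{-1}Q') X`` with annotations preserved.

    Accepts either an :class:`ExtendedMatrix` (returned as a new
    ExtendedMatrix) or a plain array.
    """
    if isinstance(X, ExtendedMatrix):
        return X.with_values(_project_array(X.values, design))
    return _project_array(np.asarray(X, dtype=float), design)
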