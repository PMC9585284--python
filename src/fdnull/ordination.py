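"""Principal coordinates analysis with negative-eigenvalue corrections.

Gower dissimilarities on mixed traits are generally non-Euclidean, so the
double-centered matrix can have negative eigenvalues. Three remedies are
offered: taking the square root of the dissimilarities before centering
(``sqrt``, the default — the square-rooted Gower coefficient is metric),
Cailliez's additive constant on the dissimilarities, or Lingoes' additive
constant on the squared dissimilarities. ``none`` embeds only the positive
axes and warns about the discarded negative share.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from skbio import DistanceMatrix

from .errors import NonEuclideanWarning, OrdinationError

CORRECTIONS = ("none", "sqrt", "cailliez", "lingoes")

_EIG_TOL = 1e-10


@dataclass
class Ordination:
    """Species coordinates on the retained principal axes.

    ``coordinates`` is species x axes with eigenvalues descending;
    ``proportion_explained`` is each positive eigenvalue over their sum;
    ``negative_share`` is sum(|negative eigenvalues|)/sum(|eigenvalues|) of
    the *corrected* matrix (0 when a correction succeeded).
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray
    correction: str
    negative_share: float

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axes(self, k: int) -> np.ndarray:
        if k > self.n_axes:
            raise OrdinationError(f"requested {k} axes but only {self.n_axes} are positive")
        return self.coordinates.to_numpy()[:, :k]


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _cailliez_constant(d: np.ndarray) -> float:
    # largest real eigenvalue of the 2n x 2n block matrix [[0, 2*D1],[-I, -4*D2]]
    # with D1 the centered -0.5*d^2 and D2 the centered -0.5*d matrices
    n = d.shape[0]
    delta1 = _gower_center(d)
    a2 = -0.5 * d
    row = a2.mean(axis=1, keepdims=True)
    col = a2.mean(axis=0, keepdims=True)
    delta2 = a2 - row - col + a2.mean()
    block = np.block(
        [[np.zeros((n, n)), 2.0 * delta1], [-np.eye(n), -4.0 * delta2]]
    )
    eigs = np.linalg.eigvals(block)
    return float(np.max(eigs.real))


def pcoa(dm: DistanceMatrix, correction: str = "sqrt", k: int | str = "max") -> Ordination:
    """Embed a distance matrix into Euclidean coordinates.

    Parameters
    ----------
    dm
        Symmetric, hollow dissimilarity matrix over >= 3 species.
    correction
        ``none``, ``sqrt`` (default), ``cailliez`` or ``lingoes``.
    k
        Number of axes to retain, or ``"max"`` for all positive axes.
    """
    if correction not in CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}; expected one of {CORRECTIONS}")
    d = dm.data.astype(float)
    n = d.shape[0]
    if n < 3:
        raise OrdinationError(f"PCoA needs >= 3 species, got {n}")

    off = ~np.eye(n, dtype=bool)
    if correction == "sqrt":
        d = np.sqrt(d)
    elif correction == "cailliez":
        c = _cailliez_constant(d)
        if c > _EIG_TOL:
            d = d + np.where(off, c, 0.0)
    elif correction == "lingoes":
        eigs0 = eigh(_gower_center(d), eigvals_only=True)
        c = -float(eigs0.min())
        if c > _EIG_TOL:
            d = np.sqrt(np.where(off, d**2 + 2.0 * c, 0.0))

    b = _gower_center(d)
    eigvals, eigvecs = eigh((b + b.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    scale = max(1.0, float(np.abs(eigvals).max()))
    positive = eigvals > _EIG_TOL * scale
    if not positive.any():
        raise OrdinationError("no positive eigenvalues; the matrix cannot be embedded")
    neg_mass = float(np.abs(eigvals[eigvals < -_EIG_TOL * scale]).sum())
    negative_share = neg_mass / float(np.abs(eigvals).sum())
    if correction == "none" and negative_share > 0:
        warnings.warn(
            f"non-Euclidean distances: negative eigenvalues carry "
            f"{negative_share:.1%} of the total magnitude",
            NonEuclideanWarning,
            stacklevel=2,
        )

    pos_vals = eigvals[positive]
    coords = eigvecs[:, positive] * np.sqrt(pos_vals)
    n_pos = coords.shape[1]
    if k != "max":
        if int(k) > n_pos:
            raise OrdinationError(f"requested {k} axes but only {n_pos} are positive")
        coords = coords[:, : int(k)]
        pos_vals = pos_vals[: int(k)]
    frame = pd.DataFrame(
        coords, index=list(dm.ids), columns=[f"PCo{i + 1}" for i in range(coords.shape[1])]
    )
    return Ordination(
        coordinates=frame,
        eigenvalues=pos_vals,
        proportion_explained=pos_vals / eigvals[positive].sum(),
        correction=correction,
        negative_share=negative_share,
    )
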