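"""Classical (Torgerson) multidimensional scaling of expression distances.

Pairwise Euclidean distances are computed either between individual samples
or between donors after concatenating each donor's per-timepoint profiles
feature-wise (the combined time-course view).  Classical MDS double-centers
the squared distance matrix, B = -1/2 J D^2 J, and embeds labels on the top
eigenvectors scaled by the square roots of the (positive) eigenvalues.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .containers import CohortDesign, ExpressionMatrix


@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray  # symmetric, zero-diagonal
    groups: pd.Series | None = None  # optional label -> group mapping

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        if (d < -1e-12).any():
            raise ValueError("distances must be non-negative")
        self.d = d


@dataclass
class MdsEmbedding:
    coordinates: pd.DataFrame  # labels x dims, column-centered
    eigenvalues: np.ndarray  # all eigenvalues, non-increasing
    goodness_of_fit: float  # positive-eigenvalue mass captured by k dims


def euclidean_distances(
    matrix: ExpressionMatrix,
    design: CohortDesign,
    concat_mode: str = "per_donor_all_times",
    time_h: float | None = None,
) -> DistanceMatrix:
    """Pairwise Euclidean distances between samples or donor time-courses.

    In ``per_donor_all_times`` mode each donor's per-timepoint columns are
    concatenated feature-wise; time points missing for any donor are dropped
    for all donors so every vector has equal length.  ``per_sample`` mode
    uses individual sample columns (optionally restricted to one time point).
    """
    matrix.require_stage("log2", "batchcorr")
    X = matrix.data
    if concat_mode == "per_donor_all_times":
        donors = design.donors
        # keep only time points every donor has
        common = [
            t
            for t in design.time_points
            if all(t in design.donor_samples(d)["time_h"].values for d in donors)
        ]
        if not common:
            raise ValueError("no time point is shared by all donors")
        vectors, labels = [], []
        for d in donors:
            sub = design.donor_samples(d)
            cols = [sub.index[sub["time_h"] == t][0] for t in common]
            vectors.append(X[cols].to_numpy().ravel(order="F"))
            labels.append(d)
        groups = pd.Series({d: design.group_of_donor(d) for d in labels})
        V = np.stack(vectors)
    elif concat_mode == "per_sample":
        ids = design.sample_ids if time_h is None else design.samples_at(time_h=time_h)
        labels = list(ids)
        V = X[ids].to_numpy().T
        groups = design.table.loc[ids, "group"]
    else:
        raise ValueError(f"unknown concat_mode {concat_mode!r}")
    if len(labels) < 3:
        raise ValueError("need at least 3 labels for a distance matrix")
    D = squareform(pdist(V, metric="euclidean"))
    return DistanceMatrix(labels, D, groups=groups)


def classical_mds(dist: DistanceMatrix, k: int = 2) -> MdsEmbedding:
    """Torgerson scaling of a distance matrix into ``k`` dimensions.

    Negative eigenvalues (non-Euclidean distance matrices) are reported but
    never used for coordinates.
    """
    D = dist.d
    n = D.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} labels for a {k}-dim embedding")
    if np.allclose(D, 0.0):
        raise ValueError("all-zero distance matrix cannot be embedded")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    lam = np.clip(eigval[:k], 0.0, None)
    coords = eigvec[:, :k] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)  # numerically exact centering
    pos = eigval[eigval > 0]
    gof = float(lam.sum() / pos.sum()) if pos.size else 0.0
    cols = [f"dim{i + 1}" for i in range(k)]
    return MdsEmbedding(
        coordinates=pd.DataFrame(coords, index=pd.Index(dist.labels, name="label"), columns=cols),
        eigenvalues=eigval,
        goodness_of_fit=gof,
    )
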