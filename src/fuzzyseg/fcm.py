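"""Classical fuzzy C-means on image intensities.

The algorithm partitions the in-mask voxels ``M = {m_1..m_n}`` into ``f``
fuzzy clusters by minimising the membership-weighted within-cluster scatter

    E_l(B, A) = sum_x sum_y b_xy^l * ||m_y - a_x||^2,

subject to unit column sums of the membership matrix ``B`` (every voxel's
memberships sum to one) and strictly positive row sums (no empty cluster).
Setting the gradient of the Lagrangian to zero yields the familiar
alternating updates: centers are membership-weighted means, memberships are
inverse-distance ratios raised to ``-1/(l-1)``. Voxels that coincide exactly
with one or more centers are singular points of the membership formula and
receive their membership split equally over the coinciding centers.

Module-level functions implement the individual updates; the
:class:`FuzzyCMeans` model wraps them in the statsmodels-style
build-then-``fit()`` idiom and returns a :class:`FCMResults`.
"""

from __future__ import annotations

import numpy as np

from .exceptions import (
    DegenerateCentersError,
    DegenerateClusterError,
    DimensionError,
    DomainError,
    InfeasibleError,
)
from .image import OUTSIDE_LABEL, GrayImage, as_gray_image

__all__ = [
    "fcm_cost",
    "update_centers",
    "update_membership",
    "defuzzify",
    "FuzzyCMeans",
    "FCMResults",
]


# ---------------------------------------------------------------------------
# elementary updates
# ---------------------------------------------------------------------------

def _flat(image) -> np.ndarray:
    return as_gray_image(image).masked_values()


def _check_B(B: np.ndarray, n: int) -> np.ndarray:
    B = np.asarray(B, dtype=float)
    if B.ndim != 2 or B.shape[1] != n:
        raise DimensionError(
            f"membership matrix must be f x n with n={n}, got {B.shape}"
        )
    return B


def fcm_cost(image, membership, centers, fuzzifier: float = 2.0) -> float:
    """Weighted within-cluster scatter sum_x sum_y b_xy^l r_xy^2.

    ``r_xy`` is the Euclidean distance from voxel ``y`` to center ``x`` in
    intensity space.
    """
    m = _flat(image)
    B = _check_B(membership, m.size)
    a = np.asarray(centers, dtype=float)
    if a.size != B.shape[0]:
        raise DimensionError("centers and membership disagree on cluster count")
    r2 = (m[None, :] - a[:, None]) ** 2
    return float(np.sum(B**fuzzifier * r2))


def update_centers(image, membership, fuzzifier: float = 2.0) -> np.ndarray:
    """Membership-weighted mean intensities, one per cluster.

    a_x = sum_y b_xy^l m_y / sum_y b_xy^l. Raises
    :class:`DegenerateClusterError` when a cluster's total (fuzzified)
    membership vanishes, which violates the positive row-sum constraint.
    """
    m = _flat(image)
    B = _check_B(membership, m.size)
    w = B**fuzzifier
    denom = w.sum(axis=1)
    if np.any(denom <= 0.0):
        raise DegenerateClusterError("a cluster has zero total membership")
    return (w @ m) / denom


def _memberships_from_sq_distances(d2: np.ndarray, fuzzifier: float) -> np.ndarray:
    """Columnwise b propto d2^{-1/(l-1)} with equal split on zero distances.

    Shared by the Euclidean and kernel-induced updates: both reduce to
    normalising inverse powers of a nonnegative per-cluster "distance"
    matrix, and both inherit the same singular-point rule — a voxel at zero
    distance from one or more clusters splits its membership equally over
    those clusters (the limit of the general formula).
    """
    expo = 1.0 / (fuzzifier - 1.0)
    with np.errstate(divide="ignore", over="ignore"):
        inv = d2 ** (-expo)
    B = np.empty_like(d2)
    finite = np.isfinite(inv)
    bad_cols = ~finite.all(axis=0)
    ok = ~bad_cols
    B[:, ok] = inv[:, ok] / inv[:, ok].sum(axis=0)
    if bad_cols.any():
        # voxels sitting exactly on >=1 center: equal split over the
        # zero-distance clusters, zero elsewhere
        sing = ~finite[:, bad_cols]
        B[:, bad_cols] = sing / sing.sum(axis=0)
    return B


def update_membership(image, centers, fuzzifier: float = 2.0) -> np.ndarray:
    """Inverse-distance membership update.

    b_xy = [ sum_g (r_xy / r_gy)^{2/(l-1)} ]^{-1} for voxels distinct from
    every center; voxels coinciding with a center get the equal-split
    singular rule. Columns sum to one.
    """
    m = _flat(image)
    a = np.asarray(centers, dtype=float)
    if a.ndim != 1 or a.size < 2:
        raise DimensionError("need a 1-D array of >= 2 centers")
    if np.unique(a).size != a.size:
        raise DegenerateCentersError("cluster centers must be distinct")
    if fuzzifier <= 1.0:
        raise DomainError("fuzzifier must exceed 1")
    r2 = (m[None, :] - a[:, None]) ** 2
    return _memberships_from_sq_distances(r2, fuzzifier)


def defuzzify(membership, shape=None, mask=None) -> np.ndarray:
    """Crisp labels by maximum membership; ties go to the lowest cluster.

    With ``shape`` given, labels are embedded into the full image geometry
    and voxels outside ``mask`` receive :data:`OUTSIDE_LABEL`.
    """
    B = np.asarray(membership, dtype=float)
    labels = np.argmax(B, axis=0).astype(np.int32)
    if shape is None:
        return labels
    if mask is None:
        return labels.reshape(shape)
    out = np.full(shape, OUTSIDE_LABEL, dtype=np.int32)
    out[mask] = labels
    return out


# ---------------------------------------------------------------------------
# initialization shared with the kernel variant
# ---------------------------------------------------------------------------

def random_membership(n_clusters: int, n: int, seed: int) -> np.ndarray:
    """Seeded uniform random membership matrix with unit column sums."""
    rng = np.random.default_rng(seed)
    B = rng.random((n_clusters, n))
    return B / B.sum(axis=0)


def quantile_centers(values: np.ndarray, n_clusters: int) -> np.ndarray:
    """Deterministic centers at evenly spaced intensity quantiles."""
    q = (np.arange(n_clusters) + 0.5) / n_clusters
    a = np.quantile(values, q)
    if np.unique(a).size != a.size:  # heavily quantised data: fall back
        lo, hi = values.min(), values.max()
        a = np.linspace(lo, hi, n_clusters + 2)[1:-1]
    return a


def _check_feasible(values: np.ndarray, n_clusters: int) -> None:
    if n_clusters < 2:
        raise DomainError("need at least 2 clusters")
    if np.unique(values).size < n_clusters:
        raise InfeasibleError(
            f"fewer than {n_clusters} distinct intensities in the mask"
        )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class FuzzyCMeans:
    """Classical fuzzy C-means segmentation model for a grayscale image.

    Parameters
    ----------
    image
        :class:`~fuzzyseg.image.GrayImage` or plain array (2-D/3-D).
    n_clusters
        Number of tissue classes ``f`` (>= 2).
    fuzzifier
        Membership softness exponent ``l`` > 1; 2.0 is the field standard.
    tol
        Convergence threshold on the max-abs center change between
        successive iterations.
    max_iter
        Iteration cap.
    init
        ``"random"`` (seeded random membership matrix) or ``"quantile"``
        (deterministic centers at evenly spaced intensity quantiles).

    Examples
    --------
    >>> res = FuzzyCMeans(img, n_clusters=3).fit(seed=0)
    >>> res.centers
    array([...])
    """

    def __init__(self, image, n_clusters: int = 3, fuzzifier: float = 2.0,
                 tol: float = 1e-4, max_iter: int = 300, init: str = "random"):
        self.image = as_gray_image(image)
        if fuzzifier <= 1.0:
            raise DomainError("fuzzifier must exceed 1")
        if tol <= 0 or max_iter < 1:
            raise DomainError("tol must be > 0 and max_iter >= 1")
        if init not in ("random", "quantile"):
            raise DomainError(f"unknown init {init!r}")
        self.n_clusters = int(n_clusters)
        self.fuzzifier = float(fuzzifier)
        self.tol = float(tol)
        self.max_iter = int(max_iter)
        self.init = init

    def fit(self, seed: int = 0) -> "FCMResults":
        """Run the alternating optimisation to convergence."""
        m = self.image.masked_values()
        _check_feasible(m, self.n_clusters)
        if self.init == "random":
            B0 = random_membership(self.n_clusters, m.size, seed)
            a = update_centers(self.image, B0, self.fuzzifier)
        else:
            a = quantile_centers(m, self.n_clusters)
        cost_trace = []
        n_iter = 0
        for n_iter in range(1, self.max_iter + 1):
            B = update_membership(self.image, a, self.fuzzifier)
            a_new = update_centers(self.image, B, self.fuzzifier)
            cost_trace.append(fcm_cost(self.image, B, a_new, self.fuzzifier))
            shift = float(np.max(np.abs(a_new - a)))
            a = a_new
            if shift < self.tol:
                break
        order = np.argsort(a, kind="stable")
        return FCMResults(self, B[order], a[order], n_iter,
                          np.asarray(cost_trace))


class FCMResults:
    """Fitted fuzzy partition: memberships, centers, labels, diagnostics.

    Attributes
    ----------
    membership : (f, n) array over in-mask voxels, columns sum to 1.
    centers : (f,) array of cluster center intensities, ascending.
    n_iter : iterations run.
    cost_trace : per-iteration cost values (non-increasing).
    """

    algorithm = "fcm"

    def __init__(self, model, membership, centers, n_iter, cost_trace):
        self.model = model
        self.membership = membership
        self.centers = centers
        self.n_iter = int(n_iter)
        self.cost_trace = cost_trace

    # centers expressed in the units of the input image; identical to
    # .centers for classical FCM, overridden by the kernel variant
    @property
    def centers_gray(self) -> np.ndarray:
        return self.centers

    @property
    def labels_flat(self) -> np.ndarray:
        return defuzzify(self.membership)

    def label_map(self) -> np.ndarray:
        """Crisp labels in image geometry; OUTSIDE_LABEL beyond the mask."""
        img = self.model.image
        return defuzzify(self.membership, img.shape, img.mask)

    def membership_volumes(self) -> np.ndarray:
        """Memberships embedded as a (..., f) stack in image geometry."""
        img = self.model.image
        return np.stack(
            [img.embed(row, fill=0.0) for row in self.membership], axis=-1
        )

    # data and centers the partition was actually optimised against;
    # the kernel variant overrides these with its fuzzified working signal
    def _fit_domain(self):
        return self.model.image, self.centers

    def validity(self, fuzzifier: float | None = None):
        """Partition-quality report (Vpc, Vpe, Vxb) for this fit.

        The Xie-Beni index is evaluated in the intensity domain the model
        was fitted on, with the fitted centers — the partition is judged
        against the data it explains. Vpc/Vpe depend on the membership
        matrix only.
        """
        from .validity import validity_report

        l = self.model.fuzzifier if fuzzifier is None else fuzzifier
        image, centers = self._fit_domain()
        return validity_report(image, self.membership, centers, l)

    def summary(self) -> str:
        rep = self.validity()
        img = self.model.image
        lines = [
            f"{type(self.model).__name__} segmentation results",
            "=" * 46,
            f"voxels (in mask):   {img.n_voxels}",
            f"clusters:           {self.centers.size}",
            f"fuzzifier l:        {self.model.fuzzifier:g}",
            f"iterations:         {self.n_iter}",
            f"centers (gray):     "
            + ", ".join(f"{c:.4g}" for c in self.centers_gray),
            f"Vpc (crispness):    {rep.vpc:.4f}",
            f"Vpe (entropy):      {rep.vpe:.4f}",
            f"Vxb (Xie-Beni):     {rep.vxb:.6g}",
        ]
        return "\n".join(lines)

    def plot_segmentation(self, slice_index=None, ax=None):
        """Show the (central) label-map slice; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        labels = self.label_map()
        if labels.ndim == 3:
            k = labels.shape[-1] // 2 if slice_index is None else slice_index
            labels = labels[..., k]
        if ax is None:
            _, ax = plt.subplots()
        ax.imshow(np.ma.masked_equal(labels, OUTSIDE_LABEL),
                  interpolation="nearest")
        ax.set_title(f"{self.algorithm} segmentation")
        ax.axis("off")
        return ax
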