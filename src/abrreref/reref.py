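"""Reference reconstructions: average, mean mastoid, and REST.

All scalp EEG is a potential difference against some reference, and the
reference choice changes amplitudes (never latencies — every method here is
a fixed linear map across channels applied identically at every sample):

* **AR** (average reference): subtract the instantaneous mean of all
  channels.  Unbiased only in the limit of dense whole-head coverage.
* **MM** (mean mastoid): subtract the mean of the two mastoid electrodes.
  For a vertex-positive / mastoid-negative far-field source this *adds*
  signal at the vertex.
* **REST** (reference electrode standardization technique): approximately
  re-reference to a point at infinity.  Given an infinity-referenced lead
  field G of an equivalent source layer and its average-referenced version
  G_avg (G with the channel mean of each column removed), the transfer
  matrix is T = G G_avg^+ ; applied to average-referenced data it restores
  the potential the montage would have measured against infinity, because
  data and lead field are linked by the same (equivalent) sources.

The three operators are exposed both as scikit-learn style transformers
operating on (n_samples, n_channels) arrays — so they compose with sklearn
pipelines — and as plain functions on (channels, samples) arrays matching
the rest of this package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .forward import LeadField

__all__ = [
    "ReferenceTransform",
    "build_rest_transform",
    "to_average_reference",
    "to_mean_mastoid",
    "to_rest",
    "rereference_waveform",
    "AverageReference",
    "MeanMastoidReference",
    "RESTReference",
    "SVD_RTOL",
]

#: Relative singular-value cutoff for the REST pseudo-inverse.  G_avg is
#: rank-deficient by construction (column centring), so the truncation is
#: explicit to make conditioning reproducible.
SVD_RTOL = 1e-6


@dataclass(frozen=True)
class ReferenceTransform:
    """A channels_out x channels_in linear re-referencing operator."""

    method: str
    matrix: np.ndarray
    channel_names: tuple[str, ...]
    leadfield_hash: str = ""

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.channel_names),) * 2:
            raise ValueError("matrix must be square over the channel set")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "channel_names", tuple(self.channel_names))

    def apply(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data)
        if data.shape[0] != self.matrix.shape[1]:
            raise ValueError(
                f"data has {data.shape[0]} channels, transform expects "
                f"{self.matrix.shape[1]}")
        return self.matrix @ data


# ---------------------------------------------------------------------------
# Functional interface ((channels, samples) arrays)
# ---------------------------------------------------------------------------

def to_average_reference(data: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous channel mean from every channel."""
    data = np.asarray(data)
    if data.shape[0] < 2:
        raise ValueError("average reference needs at least two channels")
    return data - data.mean(axis=0, keepdims=True)


def to_mean_mastoid(data: np.ndarray, channel_names: list[str],
                    m1_label: str = "M1", m2_label: str = "M2") -> np.ndarray:
    """Subtract the mean of the two mastoid channels from every channel."""
    names = list(channel_names)
    for lab in (m1_label, m2_label):
        if lab not in names:
            raise KeyError(f"mastoid channel {lab!r} not in the data")
    data = np.asarray(data)
    mast = 0.5 * (data[names.index(m1_label)] + data[names.index(m2_label)])
    return data - mast


def build_rest_transform(leadfield: LeadField, svd_rtol: float = SVD_RTOL) -> ReferenceTransform:
    """REST transfer matrix T = G pinv(G_avg) from an infinity lead field.

    ``leadfield`` rows must be exactly the channels to be re-referenced
    (scalp + mastoids; the physical reference channel, identically zero in
    acquired data, is excluded).  The pseudo-inverse truncates singular
    values below ``svd_rtol`` times the largest; a warning is raised if
    G_avg loses more than the one rank the centring removes.
    """
    g = leadfield.matrix
    g_avg = g - g.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(g_avg, full_matrices=False)
    keep = s > svd_rtol * s[0]
    if keep.sum() < g.shape[0] - 1:
        warnings.warn(
            f"average-referenced lead field has rank {int(keep.sum())} < "
            f"{g.shape[0] - 1}: REST transform is poorly conditioned",
            RuntimeWarning, stacklevel=2)
    pinv = (vt[keep].T / s[keep]) @ u[:, keep].T
    t = g @ pinv
    return ReferenceTransform("REST", t, leadfield.channel_names, leadfield.montage_hash)


def to_rest(data: np.ndarray, transform: ReferenceTransform) -> np.ndarray:
    """Centre across channels, then apply the REST transfer matrix.

    The centring makes the operation invariant to whatever (common-mode)
    reference the input carries: any scalp electrode reference, the average
    reference, or REST output itself (idempotence).
    """
    if transform.method != "REST":
        raise ValueError(f"expected a REST transform, got {transform.method!r}")
    data = np.asarray(data)
    centred = data - data.mean(axis=0, keepdims=True)
    return transform.apply(centred)


def rereference_waveform(avg, method: str, rest_transform: ReferenceTransform | None = None,
                         m1_label: str = "M1", m2_label: str = "M2"):
    """Re-reference an :class:`~abrreref.preprocess.AveragedWaveform` (or a
    :class:`~abrreref.simulate.ContinuousRecording`) and retag it."""
    from dataclasses import replace as _replace

    method = method.upper()
    if method == "AR":
        op = to_average_reference
    elif method == "MM":
        def op(d):
            return to_mean_mastoid(d, list(avg.channel_names), m1_label, m2_label)
    elif method == "REST":
        if rest_transform is None:
            raise ValueError("REST re-referencing needs a ReferenceTransform")
        if tuple(rest_transform.channel_names) != tuple(avg.channel_names):
            raise ValueError("REST transform channels do not match the data")
        def op(d):
            return to_rest(d, rest_transform)
    else:
        raise ValueError(f"unknown reference method {method!r}")
    data = op(avg.data).astype(avg.data.dtype, copy=False)
    noise = getattr(avg, "noise_estimate", None)
    if noise is not None:
        noise = op(noise)  # linear map: the residual-noise waveform transforms like the data
    try:
        return _replace(avg, data=data, reference=method, noise_estimate=noise)
    except TypeError:  # objects without a noise_estimate field (e.g. recordings)
        return _replace(avg, data=data, reference=method)


# ---------------------------------------------------------------------------
# scikit-learn style transformers ((n_samples, n_channels) arrays)
# ---------------------------------------------------------------------------

class _BaseReference(TransformerMixin, BaseEstimator):
    """Shared fit/transform plumbing for the reference transformers."""

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be (n_samples, n_channels)")
        self.n_features_in_ = X.shape[1]
        self.matrix_ = self._build_matrix(X.shape[1])
        return self

    def transform(self, X):
        check_is_fitted(self, "matrix_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(f"X must be (n_samples, {self.n_features_in_})")
        return X @ self.matrix_.T


class AverageReference(_BaseReference):
    """Average re-referencing as a transformer: x -> x - mean(x).

    Fitted attribute ``matrix_`` is the (n_channels, n_channels) operator
    I - 1/n; its rows sum to zero, so any common-mode signal is removed.
    """

    def _build_matrix(self, n: int) -> np.ndarray:
        if n < 2:
            raise ValueError("average reference needs at least two channels")
        return np.eye(n) - np.full((n, n), 1.0 / n)


class MeanMastoidReference(_BaseReference):
    """Mean-mastoid re-referencing as a transformer.

    ``channel_names`` fixes the column order of X; ``m1`` / ``m2`` name the
    mastoid channels.
    """

    def __init__(self, channel_names, m1: str = "M1", m2: str = "M2"):
        self.channel_names = channel_names
        self.m1 = m1
        self.m2 = m2

    def _build_matrix(self, n: int) -> np.ndarray:
        names = list(self.channel_names)
        if len(names) != n:
            raise ValueError("channel_names length does not match X")
        for lab in (self.m1, self.m2):
            if lab not in names:
                raise KeyError(f"mastoid channel {lab!r} not in channel_names")
        m = np.eye(n)
        m[:, names.index(self.m1)] -= 0.5
        m[:, names.index(self.m2)] -= 0.5
        return m


class RESTReference(_BaseReference):
    """REST re-referencing as a transformer.

    The fitted operator is T C where C = I - 1/n centres the data and
    T = G pinv(G_avg) is the REST transfer matrix of ``lead_field`` (whose
    channel order must match the columns of X).
    """

    def __init__(self, lead_field: LeadField, svd_rtol: float = SVD_RTOL):
        self.lead_field = lead_field
        self.svd_rtol = svd_rtol

    def _build_matrix(self, n: int) -> np.ndarray:
        if len(self.lead_field.channel_names) != n:
            raise ValueError("lead field channels do not match X columns")
        t = build_rest_transform(self.lead_field, self.svd_rtol).matrix
        centre = np.eye(n) - np.full((n, n), 1.0 / n)
        return t @ centre
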