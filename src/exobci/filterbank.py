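"""Filter-bank CSP feature extraction.

Six zero-phase Butterworth sub-bands (7-9, 10-12, 13-15, 16-20, 21-25,
26-34 Hz), one CSP spatial projection per band, and log-normalized variance
features of the first/last two CSP components (4 per band, 24 total).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg, signal

log = logging.getLogger(__name__)

DEFAULT_BANDS = ((7.0, 9.0), (10.0, 12.0), (13.0, 15.0),
                 (16.0, 20.0), (21.0, 25.0), (26.0, 34.0))

N_SELECTED = 4  # first two + last two CSP components per band


@dataclass(frozen=True)
class FilterBank:
    """Ordered bandpass sub-bands applied with a zero-phase Butterworth IIR."""

    bands: tuple = DEFAULT_BANDS
    order: int = 4

    def __post_init__(self):
        bands = tuple((float(lo), float(hi)) for lo, hi in self.bands)
        object.__setattr__(self, "bands", bands)
        for lo, hi in bands:
            if not lo < hi:
                raise ValueError(f"band ({lo}, {hi}): low edge must be below high")
            if not (7.0 <= lo and hi <= 34.0):
                raise ValueError(f"band ({lo}, {hi}) outside the 7-34 Hz envelope")
        if self.order % 2 != 0 or self.order < 2:
            raise ValueError("order must be a positive even integer")

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def n_features(self) -> int:
        return N_SELECTED * self.n_bands


def bandpass(data: np.ndarray, band: tuple, fs: float, order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth bandpass along the last axis."""
    lo, hi = band
    nyq = fs / 2.0
    if not 0.0 < lo < hi < nyq:
        raise ValueError(f"band ({lo}, {hi}) must lie strictly inside (0, {nyq})")
    sos = signal.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(data, float), axis=-1)


def _spatial_covariance(epoch: np.ndarray) -> np.ndarray:
    """Trace-normalized spatial covariance EE^T / tr(EE^T) of one epoch."""
    e = np.asarray(epoch, float)
    c = e @ e.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("epoch has zero power; covariance undefined")
    return c / tr


@dataclass
class CSPModel:
    """Full CSP projection for one band and class pair.

    Rows of ``W`` are spatial filters ordered by descending class-A variance
    ratio; ``selected_rows`` are the first and last two.
    """

    W: np.ndarray
    eigenvalues: np.ndarray        # class-A variance ratios, descending
    selected_rows: tuple
    classes: tuple = ("A", "B")

    @property
    def n_channels(self) -> int:
        return self.W.shape[1]

    def selected_filters(self) -> np.ndarray:
        return self.W[list(self.selected_rows)]


def fit_csp(epochs_a, epochs_b, shrinkage: float = 1e-4,
            classes: tuple = ("A", "B")) -> CSPModel:
    """Fit CSP from two lists of (channels x samples) epochs.

    Solves the generalized eigenproblem C_A w = lambda (C_A + C_B) w on the
    class-average normalized covariances, with shrinkage regularization
    toward the scaled identity.
    """
    if len(epochs_a) < 2 or len(epochs_b) < 2:
        raise ValueError("need at least 2 epochs per class")
    n = np.asarray(epochs_a[0]).shape[0]
    for e in list(epochs_a) + list(epochs_b):
        if np.asarray(e).shape[0] != n:
            raise ValueError("all epochs must share the channel count")
    ca = np.mean([_spatial_covariance(e) for e in epochs_a], axis=0)
    cb = np.mean([_spatial_covariance(e) for e in epochs_b], axis=0)
    return fit_csp_from_covariances(ca, cb, shrinkage=shrinkage, classes=classes)


def fit_csp_from_covariances(ca: np.ndarray, cb: np.ndarray,
                             shrinkage: float = 1e-4,
                             classes: tuple = ("A", "B")) -> CSPModel:
    n = ca.shape[0]

    def shrink(c):
        return (1.0 - shrinkage) * c + shrinkage * (np.trace(c) / n) * np.eye(n)

    ca_r, cb_r = shrink(ca), shrink(cb)
    comp = ca_r + cb_r
    try:
        evals, evecs = linalg.eigh(ca_r, comp)
    except linalg.LinAlgError:
        log.warning("composite covariance ill-conditioned; increasing shrinkage")
        bump = 1e-2
        ca_r = (1 - bump) * ca_r + bump * (np.trace(ca_r) / n) * np.eye(n)
        cb_r = (1 - bump) * cb_r + bump * (np.trace(cb_r) / n) * np.eye(n)
        evals, evecs = linalg.eigh(ca_r, ca_r + cb_r)
    # eigh returns ascending; we want descending class-A variance ratio.
    order = np.argsort(evals, kind="stable")[::-1]
    W = evecs[:, order].T
    selected = (0, 1, n - 2, n - 1)
    return CSPModel(W=W, eigenvalues=evals[order], selected_rows=selected,
                    classes=tuple(classes))


def apply_csp(epoch: np.ndarray, model: CSPModel) -> np.ndarray:
    """Project one epoch onto the selected CSP components: Z = W_sel @ E."""
    e = np.asarray(epoch, float)
    if e.shape[0] != model.n_channels:
        raise ValueError(
            f"epoch has {e.shape[0]} channels, model expects {model.n_channels}")
    return model.selected_filters() @ e


def csp_features_from_covariance(cov: np.ndarray, model: CSPModel,
                                 eps: float = 1e-300) -> np.ndarray:
    """Log-normalized component variances from a spatial covariance.

    feature_j = log( var_j / sum_k var_k ) over the selected components;
    variances are second moments, so any trace normalization of ``cov``
    cancels in the ratio.
    """
    ws = model.selected_filters()
    var = np.einsum("ij,jk,ik->i", ws, cov, ws)
    if np.any(var <= 0):
        log.warning("zero-variance CSP component; flooring at machine epsilon")
        var = np.maximum(var, np.finfo(float).tiny)
    total = var.sum()
    return np.log(np.maximum(var / total, eps))


@dataclass
class FBCSPModel:
    """One CSP model per filter-bank band; features concatenated band-major."""

    bank: FilterBank
    csp_models: list
    fs: float
    classes: tuple = ("A", "B")

    @property
    def n_features(self) -> int:
        return N_SELECTED * len(self.csp_models)

    def feature_band_component(self, index: int) -> tuple:
        """Map a flat feature index to (band, component-slot)."""
        return divmod(index, N_SELECTED)

    def mirror_index(self, index: int) -> int:
        """Within-band mirror: CSP component j pairs with component 3-j."""
        band, comp = self.feature_band_component(index)
        return band * N_SELECTED + (N_SELECTED - 1 - comp)


def band_covariances(epochs, bank: FilterBank, fs: float) -> np.ndarray:
    """Per-epoch, per-band normalized spatial covariances.

    Each epoch is filtered independently in every sub-band (no filter state
    carried between windows).  Returns (n_epochs, n_bands, N, N).
    """
    epochs = [np.asarray(e, float) for e in epochs]
    n = epochs[0].shape[0]
    out = np.empty((len(epochs), bank.n_bands, n, n))
    for bi, band in enumerate(bank.bands):
        for ei, e in enumerate(epochs):
            out[ei, bi] = _spatial_covariance(bandpass(e, band, fs, bank.order))
    return out


def fit_fbcsp_from_covariances(covs: np.ndarray, labels, classes: tuple,
                               bank: FilterBank, fs: float,
                               shrinkage: float = 1e-4) -> FBCSPModel:
    labels = np.asarray(labels)
    a, b = classes
    mask_a, mask_b = labels == a, labels == b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError(f"need >= 2 epochs in each class of {classes}")
    models = []
    for bi in range(bank.n_bands):
        ca = covs[mask_a, bi].mean(axis=0)
        cb = covs[mask_b, bi].mean(axis=0)
        models.append(fit_csp_from_covariances(ca, cb, shrinkage, classes))
    return FBCSPModel(bank=bank, csp_models=models, fs=fs, classes=tuple(classes))


def fit_fbcsp(epochs, labels, classes: tuple, bank: FilterBank | None = None,
              fs: float = 500.0, shrinkage: float = 1e-4) -> FBCSPModel:
    """Fit one CSP transformation per sub-band on labelled epochs."""
    bank = bank or FilterBank()
    covs = band_covariances(epochs, bank, fs)
    return fit_fbcsp_from_covariances(covs, labels, classes, bank, fs, shrinkage)


def features_from_covariances(covs: np.ndarray, model: FBCSPModel) -> np.ndarray:
    """(n_epochs, n_features) feature matrix from precomputed covariances."""
    n_epochs = covs.shape[0]
    out = np.empty((n_epochs, model.n_features))
    for bi, csp in enumerate(model.csp_models):
        for ei in range(n_epochs):
            out[ei, bi * N_SELECTED:(bi + 1) * N_SELECTED] = \
                csp_features_from_covariance(covs[ei, bi], csp)
    return out


def extract_features(epoch: np.ndarray, model: FBCSPModel) -> np.ndarray:
    """Feature vector (band-major, 4 per band) for a single epoch."""
    covs = band_covariances([epoch], model.bank, model.fs)
    return features_from_covariances(covs, model)[0]
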