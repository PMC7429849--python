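"""Signature refitting: decomposing 96-channel profiles into signature mixtures.

Two independent algorithms estimate the non-negative contribution of each
candidate signature to an observed profile:

* :class:`NNLSSignatureFitter` solves the non-negative least-squares problem
  ``min ||m - W^T c||_2, c >= 0`` exactly and reports relative contributions
  ``c / sum(c)`` with the relative reconstruction error as residual.

* :class:`ForwardSelectionSignatureFitter` selects signatures greedily: at
  each step every candidate gets a one-dimensional golden-section search
  over its weight, and the single coordinate update that most reduces the
  error between the weighted reconstruction and the profile is accepted;
  iteration stops when the improvement falls below ``error_tol``, weights
  below ``weight_cutoff`` (relative) are zeroed, and the unexplained
  profile mass is the residual.

Both are scikit-learn estimators operating on row matrices of profiles;
``fit_nnls`` / ``fit_forward_selection`` are single-profile conveniences.
A signature is accepted by the consensus rule only if both algorithms assign
it at least ``min_contrib`` and its own cosine similarity with the observed
profile exceeds ``min_cos``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .profiles import Profile96
from .signatures import SignatureSet, cosine_similarity

FORWARD_SELECTION = "forward_selection"
NNLS = "nnls"


@dataclass
class FitResult:
    """Per-method decomposition of one profile."""

    method: str
    contributions: pd.Series  # signature name -> fraction in [0, 1]
    residual: float
    reconstructed: np.ndarray  # 96 relative frequencies
    reconstruction_cosine: float

    def __post_init__(self) -> None:
        if (self.contributions < -1e-12).any():
            raise ValueError("negative contributions")
        if not 0.0 <= self.reconstruction_cosine <= 1.0 + 1e-12:
            raise ValueError("reconstruction cosine outside [0, 1]")

    @property
    def detected(self) -> list[str]:
        """Signatures with a strictly positive contribution."""
        return [s for s, c in self.contributions.items() if c > 0]


def _as_freq_matrix(X) -> np.ndarray:
    X = check_array(X, ensure_min_features=96)
    if X.shape[1] != 96:
        raise ValueError(f"expected 96 channels, got {X.shape[1]}")
    if (X < 0).any():
        raise ValueError("negative channel values")
    totals = X.sum(axis=1, keepdims=True)
    if (totals <= 0).any():
        raise ValueError("cannot fit an all-zero profile")
    return X / totals


def golden_section_min(
    f: Callable[[float], float], lo: float, hi: float, tol: float = 1e-5
) -> tuple[float, float]:
    """Golden-section minimisation of a unimodal function on [lo, hi]."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    while b - a > tol:
        if fc <= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    x = (a + b) / 2.0
    return x, f(x)


class _BaseSignatureFitter(BaseEstimator, TransformerMixin):
    """Shared scikit-learn plumbing for the two refitting algorithms."""

    def __init__(self, signatures: SignatureSet | None = None):
        self.signatures = signatures

    method: str = ""

    def _decompose(self, m: np.ndarray) -> tuple[np.ndarray, float]:
        raise NotImplementedError

    def fit(self, X, y=None):
        """Decompose each row of ``X`` (profiles as counts or frequencies)."""
        if self.signatures is None or len(self.signatures) == 0:
            raise ValueError("signatures must be a non-empty SignatureSet")
        M = _as_freq_matrix(X)
        W = self.signatures.weights
        contribs = np.zeros((M.shape[0], len(self.signatures)))
        residuals = np.zeros(M.shape[0])
        recon = np.zeros_like(M)
        cosines = np.zeros(M.shape[0])
        for i, m in enumerate(M):
            c, residual = self._decompose(m)
            contribs[i] = c
            residuals[i] = residual
            if c.sum() > 0:
                r = c @ W
                r = r / r.sum()
            else:
                r = np.zeros(96)
            recon[i] = r
            cosines[i] = cosine_similarity(m, r) if r.sum() > 0 else 0.0
        self.contributions_ = contribs
        self.residuals_ = residuals
        self.reconstructed_ = recon
        self.reconstruction_cosines_ = cosines
        self.n_features_in_ = 96
        return self

    def transform(self, X):
        """Contribution matrix for ``X`` (stateless per-row decomposition)."""
        check_is_fitted(self, "contributions_")
        return type(self)(**self.get_params()).fit(X).contributions_

    def fit_result(self, profile: Profile96 | np.ndarray) -> FitResult:
        """Decompose a single profile into a :class:`FitResult`."""
        m = profile.freqs if isinstance(profile, Profile96) else np.asarray(profile, float)
        self.fit(m.reshape(1, -1))
        return FitResult(
            method=self.method,
            contributions=pd.Series(
                self.contributions_[0], index=list(self.signatures.names)
            ),
            residual=float(self.residuals_[0]),
            reconstructed=self.reconstructed_[0],
            reconstruction_cosine=float(self.reconstruction_cosines_[0]),
        )


class NNLSSignatureFitter(_BaseSignatureFitter):
    """Exact non-negative least-squares refitting.

    Contributions are normalized to sum 1; the residual is the relative
    reconstruction error ``||m - W^T c|| / ||m||``.
    """

    method = NNLS

    def _decompose(self, m: np.ndarray) -> tuple[np.ndarray, float]:
        W = self.signatures.weights
        c, rnorm = nnls(W.T, m)
        total = c.sum()
        residual = rnorm / np.linalg.norm(m)
        if total <= 0:
            return np.zeros_like(c), 1.0
        return c / total, float(residual)


class ForwardSelectionSignatureFitter(_BaseSignatureFitter):
    """Greedy forward-selection refitting with golden-section weight search.

    ``weight_cutoff`` zeroes signatures below 6% relative weight (the
    reference forward-selection default); ``error_tol`` stops iteration once
    the L2 error improvement is negligible. Ties between equally good
    candidates break toward the lexicographically first signature name. The
    residual is ``1 - sum(contributions)``: profile mass left unexplained
    or discarded by the cutoff.
    """

    method = FORWARD_SELECTION

    def __init__(
        self,
        signatures: SignatureSet | None = None,
        weight_cutoff: float = 0.06,
        error_tol: float = 1e-3,
        max_iter: int = 100,
    ):
        super().__init__(signatures=signatures)
        self.weight_cutoff = weight_cutoff
        self.error_tol = error_tol
        self.max_iter = max_iter

    def _error(self, w: np.ndarray, m: np.ndarray) -> float:
        """L2 norm of (weighted reconstruction - profile), unnormalized.

        Both the profile and every signature row sum to 1, so absolute
        weights are meaningful: a perfect decomposition has weights summing
        to 1 and any shortfall is unexplained profile mass (the residual).
        Minimising this norm also minimises the sum of squares. Keeping the
        reconstruction unnormalized makes the weight search well-posed — a
        scale-free error would be flat in the first signature's weight.
        """
        return float(np.linalg.norm(w @ self.signatures.weights - m))

    def _decompose(self, m: np.ndarray) -> tuple[np.ndarray, float]:
        k = len(self.signatures)
        order = np.argsort(np.asarray(self.signatures.names))  # tie-break order
        w = np.zeros(k)
        error = self._error(w, m)
        for _ in range(self.max_iter):
            # for every candidate, golden-section search over its total
            # weight (an update may lower a weight set too high earlier);
            # accept the single best coordinate update per iteration
            best: tuple[float, int, float] | None = None
            for idx in order:
                def objective(x: float, idx=idx) -> float:
                    trial = w.copy()
                    trial[idx] = x
                    return self._error(trial, m)

                x, fx = golden_section_min(objective, 0.0, 1.0)
                if best is None or fx < best[0] - 1e-15:
                    best = (fx, idx, x)
            assert best is not None
            new_error, idx, x = best
            if error - new_error < self.error_tol:
                break
            w[idx] = x
            error = new_error
        total = w.sum()
        if total <= 0:
            return np.zeros(k), 1.0
        # the cutoff acts on relative weights; contributions stay absolute
        w[w / total < self.weight_cutoff] = 0.0
        if w.sum() > 1.0:
            w = w / w.sum()
        residual = 1.0 - w.sum()
        return w, float(residual)


def fit_nnls(profile: Profile96 | np.ndarray, sigs: SignatureSet) -> FitResult:
    """Non-negative least-squares decomposition of one profile."""
    return NNLSSignatureFitter(signatures=sigs).fit_result(profile)


def fit_forward_selection(
    profile: Profile96 | np.ndarray,
    sigs: SignatureSet,
    weight_cutoff: float = 0.06,
    error_tol: float = 1e-3,
) -> FitResult:
    """Greedy forward-selection decomposition of one profile."""
    fitter = ForwardSelectionSignatureFitter(
        signatures=sigs, weight_cutoff=weight_cutoff, error_tol=error_tol
    )
    return fitter.fit_result(profile)


def reconstruct(
    contributions: Mapping[str, float] | pd.Series, sigs: SignatureSet
) -> np.ndarray:
    """Weighted sum of signature rows, renormalized to sum 1."""
    contrib = pd.Series(contributions, dtype=float)
    unknown = set(contrib.index) - set(sigs.names)
    if unknown:
        raise ValueError(f"unknown signatures: {sorted(unknown)}")
    if (contrib < 0).any():
        raise ValueError("negative contributions")
    if contrib.sum() <= 0:
        raise ValueError("all-zero contributions")
    out = np.zeros(96)
    for name, weight in contrib.items():
        out += weight * sigs.row(name)
    return out / out.sum()


@dataclass
class ConsensusReport:
    """Outcome of the dual-algorithm consensus rule for one profile."""

    accepted: tuple[str, ...]
    contributions: pd.DataFrame  # signatures x methods
    profile_cosines: pd.Series  # cosine(signature row, observed profile)
    rejections: dict[str, str]  # signature -> primary failed criterion
    min_contrib: float
    min_cos: float


def consensus_filter(
    fit_a: FitResult,
    fit_b: FitResult,
    profile: Profile96 | np.ndarray,
    sigs: SignatureSet,
    min_contrib: float = 0.20,
    min_cos: float = 0.5,
) -> ConsensusReport:
    """Apply the three-criterion consensus rule to two independent fits.

    A signature is accepted iff (i) both methods detect it, (ii) both assign
    it at least ``min_contrib``, and (iii) its cosine similarity with the
    observed profile exceeds ``min_cos``. Rejected signatures are annotated
    with the most informative failed criterion: a signature seen by only one
    method at a reportable contribution fails (i); one never reaching
    ``min_contrib`` anywhere fails (ii); cosine failures fail (iii).
    """
    names_a = tuple(fit_a.contributions.index)
    names_b = tuple(fit_b.contributions.index)
    if names_a != names_b or set(names_a) != set(sigs.names):
        raise ValueError("fits must cover the same signature set")
    m = profile.freqs if isinstance(profile, Profile96) else np.asarray(profile, float)
    cosines = pd.Series(
        [cosine_similarity(sigs.row(n), m) for n in sigs.names],
        index=list(sigs.names),
    )
    table = pd.DataFrame(
        {fit_a.method: fit_a.contributions, fit_b.method: fit_b.contributions}
    )
    accepted: list[str] = []
    rejections: dict[str, str] = {}
    for name in sigs.names:
        ca, cb = float(fit_a.contributions[name]), float(fit_b.contributions[name])
        detected_both = ca > 0 and cb > 0
        contrib_ok = ca >= min_contrib and cb >= min_contrib
        cos_ok = float(cosines[name]) > min_cos
        if detected_both and contrib_ok and cos_ok:
            accepted.append(name)
        elif ca == 0 and cb == 0:
            rejections[name] = "i"
        elif not detected_both:
            # identified by one method only; blame (i) when that method's
            # contribution was reportable, (ii) when it was below threshold
            rejections[name] = "i" if max(ca, cb) >= min_contrib else "ii"
        elif not contrib_ok:
            rejections[name] = "ii"
        else:
            rejections[name] = "iii"
    return ConsensusReport(
        accepted=tuple(accepted),
        contributions=table,
        profile_cosines=cosines,
        rejections=rejections,
        min_contrib=min_contrib,
        min_cos=min_cos,
    )


def stringency_sweep(
    fit_a: FitResult,
    fit_b: FitResult,
    profile: Profile96 | np.ndarray,
    sigs: SignatureSet,
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8),
    min_contrib: float = 0.20,
) -> pd.DataFrame:
    """Consensus survival per signature as the cosine floor is raised."""
    out = {}
    for t in thresholds:
        report = consensus_filter(
            fit_a, fit_b, profile, sigs, min_contrib=min_contrib, min_cos=t
        )
        out[t] = pd.Series(
            [n in report.accepted for n in sigs.names], index=list(sigs.names)
        )
    return pd.DataFrame(out)
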