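"""Helstrom quantum classifier (HQC).

A binary classifier inspired by quantum state discrimination.  Each real
feature vector ``x`` (n features) is encoded into a *density pattern* — a
symmetric, positive-semidefinite, unit-trace matrix representing a quantum
state — optionally tensored with itself ``m`` times.  Each class is
summarised by its *quantum centroid* (the arithmetic mean of its density
patterns, a mixed state).  The Helstrom observable

    Lambda = w+ * rho+  -  w- * rho-

is the weighted difference of the two centroids; its positive and negative
eigenspaces define the optimal two-outcome measurement discriminating the
two classes, and

    helstrom_bound = w+ * tr(P+ rho+) + w- * tr(P- rho-)
                   = (1 + ||Lambda||_1) / 2

is the maximal probability of a correct discrimination.  A sample is
classified by comparing ``tr(P+ rho_sample)`` against 1/2.

Hyperparameters: a rescaling factor applied to the (standardized) features,
the encoding (stereographic or amplitude), the number of tensor copies m,
and the class-weight mode (equiprobable 1/2-1/2 or proportional to class
cardinalities).  The density-pattern side grows as (n+1)^m, which is the
O(n^m) cost driver of the method.
"""

from __future__ import annotations

import json
import numbers

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import InvalidParameterError, ResourceLimitError

__all__ = [
    "rescale",
    "encode_stereographic",
    "encode_amplitude",
    "encode_vector",
    "tensor_copies",
    "quantum_centroid",
    "helstrom_projectors",
    "HelstromClassifier",
]

#: numerical floor below which an eigenvalue of the Helstrom observable is
#: treated as zero and its direction assigned to the negative projector, so
#: that the two projectors always resolve the identity.
POSITIVE_EIGENVALUE_FLOOR = 1e-12

DEFAULT_MAX_SIDE = 4096

ENCODINGS = ("stereographic", "amplitude")
CLASS_WEIGHTINGS = ("equiprobable", "weighted")


def _as_vector(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise InvalidParameterError("feature vector must be 1-D and non-empty")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("feature vector must have finite entries")
    return x


def rescale(x, factor: float) -> np.ndarray:
    """Multiply every feature by a positive scalar factor.

    Rescaling is a genuine HQC hyperparameter: it moves the encoded points
    on the hypersphere and can change the geometry of the two centroids.
    """
    if not isinstance(factor, numbers.Real) or not np.isfinite(factor) or factor <= 0:
        raise InvalidParameterError(f"rescale factor must be a positive finite real, got {factor!r}")
    return _as_vector(x) * float(factor)


def _stereographic_amplitudes(x: np.ndarray) -> np.ndarray:
    # inverse stereographic projection of R^n onto the unit n-sphere:
    # a = (2 x, ||x||^2 - 1) / (||x||^2 + 1)
    s = float(x @ x)
    return np.concatenate([2.0 * x, [s - 1.0]]) / (s + 1.0)


def _amplitude_amplitudes(x: np.ndarray) -> np.ndarray:
    # append a constant 1 and normalise; the extra component retains the
    # norm information of x inside the quantum state
    s = float(x @ x)
    return np.concatenate([x, [1.0]]) / np.sqrt(s + 1.0)


def encode_stereographic(x) -> np.ndarray:
    """Encode a real vector as a rank-1 density pattern via inverse
    stereographic projection onto the unit hypersphere.

    Returns the (n+1)x(n+1) outer product ``a a^T`` of the unit amplitude
    vector ``a = (2x, ||x||^2 - 1) / (||x||^2 + 1)``.
    """
    a = _stereographic_amplitudes(_as_vector(x))
    return np.outer(a, a)


def encode_amplitude(x) -> np.ndarray:
    """Encode a real vector as a rank-1 density pattern via the
    norm-preserving amplitude map ``a = (x, 1) / sqrt(||x||^2 + 1)``."""
    a = _amplitude_amplitudes(_as_vector(x))
    return np.outer(a, a)


def encode_vector(x, encoding: str) -> np.ndarray:
    """Amplitude vector (not the outer product) for the named encoding."""
    if encoding == "stereographic":
        return _stereographic_amplitudes(_as_vector(x))
    if encoding == "amplitude":
        return _amplitude_amplitudes(_as_vector(x))
    raise InvalidParameterError(f"unknown encoding {encoding!r}; expected one of {ENCODINGS}")


def tensor_copies(rho: np.ndarray, m: int, max_side: int = DEFAULT_MAX_SIDE) -> np.ndarray:
    """m-fold tensor (Kronecker) power ``rho^(x m)`` of a density pattern.

    Taking copies of a state can only improve the distinguishability of two
    states, at the price of a matrix side growing as side(rho)^m.
    """
    if not isinstance(m, numbers.Integral) or m < 1:
        raise InvalidParameterError(f"number of copies must be an integer >= 1, got {m!r}")
    rho = np.asarray(rho, dtype=float)
    side = rho.shape[0] ** m
    if side > max_side:
        raise ResourceLimitError(
            f"tensor_copies would produce a {side}x{side} matrix "
            f"(side {rho.shape[0]}^{m}), exceeding the cap of {max_side}"
        )
    out = rho
    for _ in range(int(m) - 1):
        out = np.kron(out, rho)
    return out


def quantum_centroid(patterns) -> np.ndarray:
    """Entrywise mean of a sequence of density patterns — the mixed state
    summarising a class."""
    patterns = list(patterns)
    if not patterns:
        raise InvalidParameterError("quantum_centroid requires a non-empty sequence")
    first = np.asarray(patterns[0], dtype=float)
    acc = np.zeros_like(first)
    for p in patterns:
        p = np.asarray(p, dtype=float)
        if p.shape != first.shape:
            raise ValueError(f"mismatched density pattern shapes {p.shape} vs {first.shape}")
        acc += p
    return acc / len(patterns)


def _check_symmetric(a: np.ndarray, name: str, tol: float = 1e-8) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {a.shape}")
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError(f"{name} is not symmetric within tolerance {tol}")
    return 0.5 * (a + a.T)


def helstrom_projectors(centroid_pos, centroid_neg, weight_pos: float, weight_neg: float):
    """Spectral projectors of the Helstrom observable and the Helstrom bound.

    Builds ``Lambda = w+ rho+ - w- rho-``, eigendecomposes it, and returns
    ``(P+, P-, bound)`` where P+ projects onto the strictly positive
    eigenspace, ``P- = I - P+``, and the bound is the optimal discrimination
    probability ``w+ tr(P+ rho+) + w- tr(P- rho-)``.
    """
    rp = _check_symmetric(centroid_pos, "centroid_pos")
    rn = _check_symmetric(centroid_neg, "centroid_neg")
    if rp.shape != rn.shape:
        raise ValueError(f"centroid shapes differ: {rp.shape} vs {rn.shape}")
    if weight_pos < 0 or weight_neg < 0 or abs(weight_pos + weight_neg - 1.0) > 1e-9:
        raise InvalidParameterError("class weights must be non-negative and sum to 1")
    lam = weight_pos * rp - weight_neg * rn
    eigvals, eigvecs = np.linalg.eigh(0.5 * (lam + lam.T))
    keep = eigvals > POSITIVE_EIGENVALUE_FLOOR
    v = eigvecs[:, keep]
    p_pos = v @ v.T
    p_neg = np.eye(lam.shape[0]) - p_pos
    bound = weight_pos * float(np.sum(p_pos * rp)) + weight_neg * float(np.sum(p_neg * rn))
    return p_pos, p_neg, bound


class HelstromClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier by optimal discrimination of two quantum centroids.

    Parameters
    ----------
    rescale_factor : float, default=1.0
        Positive scalar multiplied into every (standardized) feature before
        encoding.
    encoding : {"amplitude", "stereographic"}, default="amplitude"
        Map from feature vectors to rank-1 density patterns.
    n_copies : int, default=1
        Number of tensor copies of each density pattern; the pattern side is
        ``(n_features + 1) ** n_copies``.
    class_weighting : {"equiprobable", "weighted"}, default="equiprobable"
        Centroid weights: 1/2 each, or proportional to class cardinality.
    standardize : bool, default=True
        Capture per-feature mean and population standard deviation at fit
        time and re-apply them to every sample at prediction time.  Set to
        False when the data were already standardized as a whole table.
    max_side : int, default=4096
        Cap on the density-pattern side; exceeding it raises
        :class:`~hqcolony.exceptions.ResourceLimitError`.

    Attributes
    ----------
    classes_ : ndarray of shape (2,)
        Sorted class labels; ``classes_[1]`` is the positive (colony) class.
    centroid_pos_, centroid_neg_ : ndarray
        Quantum centroids of the positive and negative class.
    weight_pos_, weight_neg_ : float
        Centroid weights (sum to 1).
    projector_pos_, projector_neg_ : ndarray
        Spectral projectors of the Helstrom observable (resolve the identity).
    helstrom_bound_ : float
        Optimal discrimination probability of the two fitted centroids.
    mean_, scale_ : ndarray of shape (n_features,)
        Standardization statistics captured at fit time (zeros/ones when
        ``standardize=False``).
    """

    def __init__(
        self,
        rescale_factor: float = 1.0,
        encoding: str = "amplitude",
        n_copies: int = 1,
        class_weighting: str = "equiprobable",
        standardize: bool = True,
        max_side: int = DEFAULT_MAX_SIDE,
    ):
        self.rescale_factor = rescale_factor
        self.encoding = encoding
        self.n_copies = n_copies
        self.class_weighting = class_weighting
        self.standardize = standardize
        self.max_side = max_side

    # -- internals ---------------------------------------------------------

    def _validate_hyperparameters(self):
        if not isinstance(self.rescale_factor, numbers.Real) or not np.isfinite(
            self.rescale_factor
        ) or self.rescale_factor <= 0:
            raise InvalidParameterError(
                f"rescale_factor must be a positive finite real, got {self.rescale_factor!r}"
            )
        if self.encoding not in ENCODINGS:
            raise InvalidParameterError(
                f"encoding must be one of {ENCODINGS}, got {self.encoding!r}"
            )
        if not isinstance(self.n_copies, numbers.Integral) or self.n_copies < 1:
            raise InvalidParameterError(
                f"n_copies must be an integer >= 1, got {self.n_copies!r}"
            )
        if self.class_weighting not in CLASS_WEIGHTINGS:
            raise InvalidParameterError(
                f"class_weighting must be one of {CLASS_WEIGHTINGS}, got {self.class_weighting!r}"
            )

    def _encoded_copies(self, X: np.ndarray) -> np.ndarray:
        """Rows of a^(x m) for every sample; the density pattern of a sample
        is the outer product of its row (so centroids are A^T A / N)."""
        side = (X.shape[1] + 1) ** self.n_copies
        if side > self.max_side:
            raise ResourceLimitError(
                f"density pattern side {X.shape[1] + 1}^{self.n_copies} = {side} "
                f"exceeds the cap of {self.max_side}"
            )
        Xs = (X - self.mean_) / self.scale_
        Xs = Xs * self.rescale_factor
        out = np.empty((X.shape[0], side))
        for i, x in enumerate(Xs):
            a = encode_vector(x, self.encoding)
            v = a
            for _ in range(self.n_copies - 1):
                v = np.kron(v, a)
            out[i] = v
        return out

    # -- sklearn API -------------------------------------------------------

    def fit(self, X, y):
        """Fit centroids, class weights and Helstrom projectors."""
        self._validate_hyperparameters()
        X, y = check_X_y(X, y, dtype=float)
        self.classes_ = unique_labels(y)
        if len(self.classes_) != 2:
            present = ", ".join(map(str, self.classes_))
            raise ValueError(
                f"HelstromClassifier is a binary classifier and requires both "
                f"classes in the training data; got only class(es) [{present}]"
            )
        self.n_features_in_ = X.shape[1]
        if self.standardize:
            self.mean_ = X.mean(axis=0)
            sd = X.std(axis=0)  # population sd, matching the table pipeline
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.mean_ = np.zeros(self.n_features_in_)
            self.scale_ = np.ones(self.n_features_in_)

        pos = y == self.classes_[1]
        amp = self._encoded_copies(X)
        a_pos, a_neg = amp[pos], amp[~pos]
        self.centroid_pos_ = a_pos.T @ a_pos / len(a_pos)
        self.centroid_neg_ = a_neg.T @ a_neg / len(a_neg)
        if self.class_weighting == "equiprobable":
            self.weight_pos_ = self.weight_neg_ = 0.5
        else:
            self.weight_pos_ = len(a_pos) / len(amp)
            self.weight_neg_ = len(a_neg) / len(amp)
        self.projector_pos_, self.projector_neg_, self.helstrom_bound_ = helstrom_projectors(
            self.centroid_pos_, self.centroid_neg_, self.weight_pos_, self.weight_neg_
        )
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Probability-like score ``tr(P+ rho_x)`` in [0, 1] per sample.

        The complementary score against P- is ``1 - score`` because the
        projectors resolve the identity and every density pattern has unit
        trace.
        """
        check_is_fitted(self)
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, but the model was fitted with "
                f"{self.n_features_in_}"
            )
        amp = self._encoded_copies(X)
        # tr(P a a^T) = a^T P a
        return np.clip(np.einsum("ij,jk,ik->i", amp, self.projector_pos_, amp), 0.0, 1.0)

    def predict_proba(self, X) -> np.ndarray:
        s = self.decision_scores(X)
        return np.column_stack([1.0 - s, s])

    def decision_function(self, X) -> np.ndarray:
        return self.decision_scores(X) - 0.5

    def predict(self, X) -> np.ndarray:
        # strict > 0.5: a tie goes to the negative (background) class
        return self.classes_[(self.decision_scores(X) > 0.5).astype(int)]

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-serializable snapshot of the fitted model."""
        check_is_fitted(self)
        return {
            "hyperparameters": self.get_params(),
            "classes": np.asarray(self.classes_).tolist(),
            "weights": [self.weight_pos_, self.weight_neg_],
            "helstrom_bound": self.helstrom_bound_,
            "centroid_pos": self.centroid_pos_.tolist(),
            "centroid_neg": self.centroid_neg_.tolist(),
            "projector_pos": self.projector_pos_.tolist(),
            "projector_neg": self.projector_neg_.tolist(),
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
        }

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, payload: dict) -> "HelstromClassifier":
        model = cls(**payload["hyperparameters"])
        model.classes_ = np.asarray(payload["classes"])
        model.weight_pos_, model.weight_neg_ = payload["weights"]
        model.helstrom_bound_ = payload["helstrom_bound"]
        model.centroid_pos_ = np.asarray(payload["centroid_pos"])
        model.centroid_neg_ = np.asarray(payload["centroid_neg"])
        model.projector_pos_ = np.asarray(payload["projector_pos"])
        model.projector_neg_ = np.asarray(payload["projector_neg"])
        model.mean_ = np.asarray(payload["mean"])
        model.scale_ = np.asarray(payload["scale"])
        model.n_features_in_ = model.mean_.shape[0]
        return model

    @classmethod
    def load(cls, path) -> "HelstromClassifier":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))
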