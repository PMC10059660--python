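"""Atom-environment fingerprints and the feature-selection toolkit.

Candidate atoms are described by fixed-length binary fingerprints restricted
to the environment of one designated center atom:

* ``Morgan`` — circular environments rooted at the center, radius 1–5;
* ``AtomPair`` — atom pairs with the center as one endpoint;
* ``TopologicalTorsion`` — 4-atom torsion paths containing the center.

All three are produced by RDKit's fingerprint generators with the
``fromAtoms`` restriction and folded to 256/512/1024/2048 bits by the
generators' native modulo hashing (collisions accepted, as is standard).
The default sweep is 5 Morgan radii x 4 widths + AtomPair x 4 + torsion x 4
= 28 descriptor recipes.

Feature selection offers the three stages used downstream — variance
threshold (VT), select-percentile (SPF), and PCA. SPF keeps the top
ceil(p% of columns) by a univariate label-association score (chi-squared on
binary bits by default), ties broken by lower column index; this exact-count
convention is implemented here (scikit-learn's percentile selector uses a
score-threshold rule that can keep a different number on ties). PCA is
mean-centered with no scaling — the variance of a bit column is meaningful —
and component signs follow the largest-|loading|-positive convention so that
fitted projections are reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from rdkit.Chem import rdFingerprintGenerator
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.feature_selection import VarianceThreshold, chi2, f_classif

from .chem import StandardMolecule
from .errors import (
    DegenerateSelectionError,
    DimensionError,
    FingerprintSpecError,
    LabelExtractionError,
    ScoringError,
)
from .sites import SOM, UNKNOWN, CandidateSite

__all__ = [
    "FAMILIES",
    "BIT_SIZES",
    "MORGAN_RADII",
    "AtomFingerprintSpec",
    "AtomFingerprint",
    "default_spec_sweep",
    "featurize_site",
    "build_feature_matrix",
    "FeatureSelector",
    "fit_variance_threshold",
    "fit_select_percentile",
    "fit_pca",
    "TopPercentileSelector",
    "apply_selectors",
]

FAMILIES = ("Morgan", "AtomPair", "TopologicalTorsion")
BIT_SIZES = (256, 512, 1024, 2048)
MORGAN_RADII = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class AtomFingerprintSpec:
    """A descriptor recipe: family, radius (Morgan only), bit width."""

    family: str
    n_bits: int
    radius: Optional[int] = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise FingerprintSpecError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.n_bits not in BIT_SIZES:
            raise FingerprintSpecError(f"n_bits must be one of {BIT_SIZES}, got {self.n_bits}")
        if self.family == "Morgan":
            if self.radius not in MORGAN_RADII:
                raise FingerprintSpecError(
                    f"Morgan radius must be in {MORGAN_RADII}, got {self.radius}"
                )
        elif self.radius is not None:
            raise FingerprintSpecError(f"radius is a Morgan-only parameter ({self.family})")

    @property
    def name(self) -> str:
        if self.family == "Morgan":
            return f"Morgan-r{self.radius}-{self.n_bits}"
        return f"{self.family}-{self.n_bits}"


def default_spec_sweep() -> list[AtomFingerprintSpec]:
    """The 28-recipe default sweep (5 Morgan radii + AP + TT, 4 widths each)."""
    sweep = [
        AtomFingerprintSpec("Morgan", n, r) for r in MORGAN_RADII for n in BIT_SIZES
    ]
    sweep += [AtomFingerprintSpec(f, n) for f in ("AtomPair", "TopologicalTorsion") for n in BIT_SIZES]
    return sweep


@dataclass(frozen=True)
class AtomFingerprint:
    """A fixed-length binary vector centered on one atom."""

    spec: AtomFingerprintSpec
    center_atom: int
    bits: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        assert self.bits.shape == (self.spec.n_bits,)


@lru_cache(maxsize=64)
def _generator(family: str, n_bits: int, radius: Optional[int]):
    if family == "Morgan":
        return rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    if family == "AtomPair":
        return rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
    return rdFingerprintGenerator.GetTopologicalTorsionGenerator(fpSize=n_bits)


def featurize_site(
    mol: StandardMolecule, atom_index: int, spec: AtomFingerprintSpec
) -> AtomFingerprint:
    """Fingerprint the environment of one atom.

    Deterministic for a fixed (canonical molecule, atom, spec); symmetry-
    equivalent atoms receive identical vectors because their rooted
    environments are isomorphic.
    """
    if not 0 <= atom_index < mol.atom_count:
        raise IndexError(
            f"atom index {atom_index} out of range for {mol.atom_count}-atom molecule"
        )
    gen = _generator(spec.family, spec.n_bits, spec.radius)
    fp = gen.GetFingerprint(mol.mol, fromAtoms=[atom_index])
    bits = np.zeros(spec.n_bits, dtype=np.uint8)
    bits[list(fp.GetOnBits())] = 1
    return AtomFingerprint(spec, atom_index, bits)


def build_feature_matrix(
    sites: Sequence[CandidateSite], spec: AtomFingerprintSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-site fingerprints into (X, y); row order follows the input.

    Labels must be resolved (SOM / non-SOM); y is 1 for SOM.
    """
    unknown = [i for i, s in enumerate(sites) if s.label == UNKNOWN]
    if unknown:
        raise LabelExtractionError(
            f"{len(unknown)} site(s) still labeled 'unknown' (first at row {unknown[0]}); "
            "attach labels before building a feature matrix"
        )
    X = np.zeros((len(sites), spec.n_bits), dtype=np.uint8)
    y = np.zeros(len(sites), dtype=np.int64)
    for i, s in enumerate(sites):
        X[i] = featurize_site(s.molecule, s.atom_index, spec).bits
        y[i] = 1 if s.label == SOM else 0
    return X, y


# --- feature selection ------------------------------------------------------


class TopPercentileSelector(BaseEstimator, TransformerMixin):
    """Keep the top ceil(percentile% of columns) by a univariate score.

    ``score_func``: "chi2" (default; non-negative features) or "f_classif".
    Ties are broken toward the lower column index; NaN scores rank last.
    scikit-learn compatible, so it can sit inside a Pipeline/GridSearchCV.
    """

    def __init__(self, percentile: float = 15.0, score_func: str = "chi2"):
        self.percentile = percentile
        self.score_func = score_func

    def fit(self, X, y):
        X = np.asarray(X)
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ScoringError("univariate scoring requires both classes present")
        func = {"chi2": chi2, "f_classif": f_classif}.get(self.score_func)
        if func is None:
            raise ScoringError(f"unknown score_func {self.score_func!r}")
        scores, _ = func(X, y)
        scores = np.where(np.isnan(scores), -np.inf, scores)
        k = int(np.ceil(self.percentile / 100.0 * X.shape[1]))
        k = max(1, min(k, X.shape[1]))
        order = np.argsort(-scores, kind="stable")  # stable => ties by lower index
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[order[:k]] = True
        self.scores_ = scores
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        return np.asarray(X)[:, self.support_mask_]

    def get_support(self):
        return self.support_mask_


class _SignFixedPCA(PCA):
    """Full-SVD PCA with the largest-|loading|-positive sign convention."""

    def __init__(self, n_components=None):
        super().__init__(n_components=n_components, svd_solver="full")

    def fit(self, X, y=None):
        super().fit(X)
        flip = np.sign(
            self.components_[np.arange(len(self.components_)),
                             np.abs(self.components_).argmax(axis=1)]
        )
        flip[flip == 0] = 1.0
        self.components_ = self.components_ * flip[:, None]
        return self

    def fit_transform(self, X, y=None):
        # route through fit+transform so the sign convention always applies
        return self.fit(X).transform(X)


@dataclass
class FeatureSelector:
    """A fitted selection stage: column mask (VT/SPF) or projection (PCA)."""

    method: str  # "VT" | "SPF" | "PCA"
    params: dict
    estimator: object = field(repr=False)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.transform(np.asarray(X))

    @property
    def support_mask(self) -> Optional[np.ndarray]:
        if self.method == "VT":
            return self.estimator.get_support()
        if self.method == "SPF":
            return self.estimator.get_support()
        return None

    @property
    def explained_variance_ratio(self) -> Optional[np.ndarray]:
        return getattr(self.estimator, "explained_variance_ratio_", None)


def fit_variance_threshold(X: np.ndarray, threshold: float = 0.0) -> FeatureSelector:
    """Drop every column with sample variance <= threshold (default: constants)."""
    X = np.asarray(X)
    if X.size == 0:
        raise DegenerateSelectionError("empty feature matrix")
    vt = VarianceThreshold(threshold=threshold)
    try:
        vt.fit(X)
    except ValueError as exc:
        raise DegenerateSelectionError(
            f"variance threshold {threshold} removes every column"
        ) from exc
    if not vt.get_support().any():  # pragma: no cover - sklearn raises above
        raise DegenerateSelectionError(f"variance threshold {threshold} removes every column")
    return FeatureSelector("VT", {"threshold": threshold}, vt)


def fit_select_percentile(
    X: np.ndarray, y: np.ndarray, percentile: float, score_func: str = "chi2"
) -> FeatureSelector:
    """Keep the top ceil(percentile%) of columns by univariate association."""
    sel = TopPercentileSelector(percentile=percentile, score_func=score_func).fit(
        np.asarray(X), np.asarray(y)
    )
    return FeatureSelector("SPF", {"percentile": percentile, "score_func": score_func}, sel)


def fit_pca(X: np.ndarray, n_components: int) -> FeatureSelector:
    """Mean-centered PCA onto the leading axes (no scaling of bit columns)."""
    X = np.asarray(X, dtype=np.float64)
    if n_components > min(X.shape):
        raise DimensionError(
            f"n_components={n_components} exceeds min(rows, cols)={min(X.shape)}"
        )
    pca = _SignFixedPCA(n_components=n_components).fit(X)
    return FeatureSelector("PCA", {"n_components": n_components}, pca)


def apply_selectors(selectors: Sequence[FeatureSelector], X: np.ndarray) -> np.ndarray:
    """Apply fitted selection stages in order."""
    out = np.asarray(X)
    for sel in selectors:
        out = sel.transform(out)
    return out
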