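"""Evaluation of SOM classifiers: site-level metrics, per-molecule top-k
accuracy, and dataset diagnostics (Tanimoto similarity, chemical-space PCA).

Site-level classification quality is summarized by sensitivity, specificity,
accuracy, F1, the Matthews correlation coefficient, and ROC AUC:

    SE  = TP / (TP + FN)
    SP  = TN / (TN + FP)
    ACC = (TP + TN) / (TP + TN + FP + FN)
    F1  = 2 TP / (2 TP + FN + FP)
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

A metric whose denominator vanishes is reported as undefined (None) and
flagged — never silently zero.

Molecule-level quality is top-k accuracy: the fraction of substrates for
which at least one true SOM appears among the k highest-ranked candidate
atoms. A substrate whose true SOM is not proposed by any candidate pattern
can never be ranked and counts as a failure at every k; the fraction of
molecules whose SOM is proposed at all is the coverage ceiling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from sklearn.metrics import roc_auc_score

from .chem import SomLabelSet, StandardMolecule
from .errors import NumericError, ReferenceMismatchError, UndefinedMetricError
from .features import fit_pca
from .model import RankedPrediction

__all__ = [
    "ConfusionCounts",
    "ClassificationMetrics",
    "EvaluationReport",
    "confusion_from_predictions",
    "classification_metrics",
    "auc_score",
    "topk_accuracy",
    "coverage_ceiling",
    "evaluation_report",
    "tanimoto_statistics",
    "chemical_space_pca",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion_from_predictions(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Count TP/FP/TN/FN at a decision threshold (predicted positive iff
    score >= threshold)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError(f"scores {scores.shape} and labels {labels.shape} differ in shape")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


@dataclass(frozen=True)
class ClassificationMetrics:
    se: Optional[float]
    sp: Optional[float]
    acc: Optional[float]
    f1: Optional[float]
    mcc: Optional[float]
    undefined: tuple[str, ...] = ()


def classification_metrics(c: ConfusionCounts) -> ClassificationMetrics:
    """SE/SP/ACC/F1/MCC from confusion counts; zero denominators -> None."""
    undefined: list[str] = []

    def ratio(name: str, num: int, den: int) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    se = ratio("SE", c.tp, c.tp + c.fn)
    sp = ratio("SP", c.tn, c.tn + c.fp)
    acc = ratio("ACC", c.tp + c.tn, c.total)
    f1 = ratio("F1", 2 * c.tp, 2 * c.tp + c.fn + c.fp)
    mcc_den = (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    if mcc_den == 0:
        undefined.append("MCC")
        mcc = None
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(mcc_den)
    return ClassificationMetrics(se, sp, acc, f1, mcc, tuple(undefined))


def auc_score(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based ROC AUC with midrank tie handling (Mann-Whitney form)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with a single class present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _check_aligned(pred: RankedPrediction, truth: SomLabelSet) -> None:
    if not pred.molecule.same_molecule_as(truth.substrate_ref):
        raise ReferenceMismatchError(
            "prediction/truth misalignment: "
            f"{pred.molecule.canonical_smiles!r} vs {truth.substrate_ref.canonical_smiles!r}"
        )


def topk_accuracy(
    predictions: Sequence[RankedPrediction],
    truths: Sequence[SomLabelSet],
    k: int,
) -> float:
    """Fraction of molecules with >= 1 true SOM among the k top-ranked sites.

    Molecules with an empty ranking (predicted non-substrates) count as
    incorrect at every k.
    """
    if len(predictions) != len(truths):
        raise ReferenceMismatchError(
            f"{len(predictions)} predictions vs {len(truths)} truth sets"
        )
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not predictions:
        raise NumericError("top-k accuracy undefined for an empty molecule list")
    correct = 0
    for pred, truth in zip(predictions, truths):
        _check_aligned(pred, truth)
        if truth.som_atom_indices & set(pred.top(k)):
            correct += 1
    return correct / len(predictions)


def coverage_ceiling(
    predictions: Sequence[RankedPrediction], truths: Sequence[SomLabelSet]
) -> float:
    """Max achievable top-k accuracy: fraction of molecules whose true SOM is
    among the proposed candidates at all."""
    covered = 0
    for pred, truth in zip(predictions, truths):
        _check_aligned(pred, truth)
        if truth.som_atom_indices & {idx for idx, _ in pred.ranked_sites}:
            covered += 1
    return covered / len(predictions) if predictions else float("nan")


@dataclass
class EvaluationReport:
    """Aggregate site-level and molecule-level evaluation."""

    se: Optional[float]
    sp: Optional[float]
    acc: Optional[float]
    f1: Optional[float]
    mcc: Optional[float]
    auc: Optional[float]
    topk: dict[int, float]
    n_molecules: int
    n_sites: int
    coverage: float
    threshold: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "SE": self.se,
            "SP": self.sp,
            "ACC": self.acc,
            "F1": self.f1,
            "MCC": self.mcc,
            "AUC": self.auc,
            "topk": {str(k): v for k, v in self.topk.items()},
            "n_molecules": self.n_molecules,
            "n_sites": self.n_sites,
            "coverage_ceiling": self.coverage,
            "threshold": self.threshold,
            "undefined": list(self.undefined),
        }


def evaluation_report(
    site_scores: Sequence[float],
    site_labels: Sequence[int],
    predictions: Sequence[RankedPrediction],
    truths: Sequence[SomLabelSet],
    threshold: float = 0.5,
    ks: Sequence[int] = (1, 2, 3),
) -> EvaluationReport:
    """Site-level metrics at a threshold plus molecule-level top-k accuracy."""
    counts = confusion_from_predictions(site_scores, site_labels, threshold)
    cm = classification_metrics(counts)
    undefined = list(cm.undefined)
    try:
        auc = auc_score(site_scores, site_labels)
    except UndefinedMetricError:
        auc = None
        undefined.append("AUC")
    topk = {int(k): topk_accuracy(predictions, truths, int(k)) for k in ks}
    return EvaluationReport(
        se=cm.se, sp=cm.sp, acc=cm.acc, f1=cm.f1, mcc=cm.mcc, auc=auc,
        topk=topk, n_molecules=len(predictions), n_sites=counts.total,
        coverage=coverage_ceiling(predictions, truths),
        threshold=threshold, undefined=tuple(undefined),
    )


# --- dataset diagnostics ----------------------------------------------------


def _whole_molecule_fps(molecules: Sequence[StandardMolecule], radius: int, n_bits: int):
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    return [gen.GetFingerprint(m.mol) for m in molecules]


def tanimoto_statistics(
    molecules: Sequence[StandardMolecule],
    radius: int = 2,
    n_bits: int = 1024,
    bin_width: float = 0.05,
) -> tuple[np.ndarray, float, tuple[np.ndarray, np.ndarray]]:
    """Pairwise Tanimoto similarity on whole-molecule Morgan fingerprints.

    Returns (matrix, mean over unordered distinct pairs, histogram of those
    pairs with the given bin width). A pair involving an empty fingerprint is
    assigned similarity 0 with a warning.
    """
    if len(molecules) < 2:
        raise NumericError("Tanimoto statistics require at least two molecules")
    fps = _whole_molecule_fps(molecules, radius, n_bits)
    if any(fp.GetNumOnBits() == 0 for fp in fps):
        warnings.warn("empty fingerprint encountered; its pair similarities are 0")
    n = len(fps)
    mat = np.ones((n, n), dtype=float)
    for i in range(n):
        if i + 1 < n:
            mat[i, i + 1:] = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
            mat[i + 1:, i] = mat[i, i + 1:]
    pairs = mat[np.triu_indices(n, k=1)]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    hist, edges = np.histogram(pairs, bins=edges)
    return mat, float(pairs.mean()), (hist, edges)


def chemical_space_pca(
    molecule_sets: dict[str, Sequence[StandardMolecule]],
    radius: int = 2,
    n_bits: int = 1024,
) -> tuple[pd.DataFrame, np.ndarray]:
    """2-D PCA of pooled whole-molecule Morgan fingerprints, tagged by set.

    Returns (coordinates DataFrame with columns set/index/pc1/pc2, explained
    variance fractions). All sets are pooled before mean-centering, so the
    clouds are directly comparable.
    """
    for name, mols in molecule_sets.items():
        if not len(mols):
            raise NumericError(f"molecule set {name!r} is empty")
    names, mols = [], []
    for name, ms in molecule_sets.items():
        for i, m in enumerate(ms):
            names.append((name, i))
            mols.append(m)
    if len(mols) < 3:
        raise NumericError("chemical-space PCA needs at least three molecules overall")
    fps = _whole_molecule_fps(mols, radius, n_bits)
    X = np.zeros((len(fps), n_bits), dtype=np.uint8)
    for i, fp in enumerate(fps):
        X[i, list(fp.GetOnBits())] = 1
    sel = fit_pca(X, 2)
    coords = sel.transform(X)
    df = pd.DataFrame(
        {
            "set": [n for n, _ in names],
            "index": [i for _, i in names],
            "pc1": coords[:, 0],
            "pc2": coords[:, 1],
        }
    )
    return df, sel.explained_variance_ratio
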