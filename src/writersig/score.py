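"""PCA-based prognostic risk score over a fixed gene signature.

The signature submatrix is standardized gene-wise, its first two principal
components are extracted, and each sample's risk score is the sum of its
PC1 and PC2 projections (the GGI-style construction).  Validation cohorts
are scored with the training standardization parameters and loadings —
never refit — and stratified at the training cutpoint.

PCA sign indeterminacy is resolved deterministically: each loading vector
is oriented so that its largest-absolute-value entry is positive.  Whether
a high score means high risk is a property of the training survival data
and is stored on the model as ``risk_direction``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ExpressionMatrix
from .errors import InputError, WritersigError

__all__ = ["ScoreModel", "fit_score", "apply_score", "stratify"]


@dataclass
class ScoreModel:
    signature_genes: list[str]
    means: np.ndarray
    sds: np.ndarray
    loadings_pc1: np.ndarray
    loadings_pc2: np.ndarray
    explained_variance: tuple[float, float]
    sign_convention: tuple[int, int]
    cutpoint: float | None = None
    risk_direction: str = "unknown"  # high_score_high_risk / high_score_low_risk
    pc2_degenerate: bool = False

    def to_json(self, path: str | Path) -> None:
        payload = {
            "signature_genes": self.signature_genes,
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "loadings_pc1": self.loadings_pc1.tolist(),
            "loadings_pc2": self.loadings_pc2.tolist(),
            "explained_variance": list(self.explained_variance),
            "sign_convention": list(self.sign_convention),
            "cutpoint": self.cutpoint,
            "risk_direction": self.risk_direction,
            "pc2_degenerate": self.pc2_degenerate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreModel":
        d = json.loads(Path(path).read_text())
        return cls(
            d["signature_genes"], np.array(d["means"]), np.array(d["sds"]),
            np.array(d["loadings_pc1"]), np.array(d["loadings_pc2"]),
            tuple(d["explained_variance"]), tuple(d["sign_convention"]),
            d["cutpoint"], d["risk_direction"], d["pc2_degenerate"],
        )


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, ExpressionMatrix):
        return X.to_frame()
    if isinstance(X, pd.DataFrame):
        return X
    raise InputError("expected an ExpressionMatrix or genes-x-samples DataFrame")


def _fix_sign(v: np.ndarray) -> tuple[np.ndarray, int]:
    i = int(np.argmax(np.abs(v)))
    if v[i] < 0:
        return -v, -1
    return v, 1


def fit_score(X, signature_genes: list[str] | None = None) -> ScoreModel:
    """Fit the two-component PCA score model on a signature submatrix.

    Genes are z-scored across samples; the first two eigenvectors of the
    gene-gene sample covariance of the standardized matrix become the
    loadings.  A zero-variance gene is an error (it cannot be
    standardized); a degenerate second component (zero eigenvalue) is
    retained but flagged.
    """
    frame = _as_frame(X)
    if signature_genes is None:
        signature_genes = list(frame.index)
    missing = [g for g in signature_genes if g not in frame.index]
    if missing:
        raise InputError(f"signature genes absent from matrix: {missing}")
    if len(signature_genes) < 2:
        raise InputError("at least 2 signature genes required")
    sub = np.ascontiguousarray(frame.loc[signature_genes].to_numpy(dtype=float))
    if sub.shape[1] < 3:
        raise InputError("at least 3 samples required")
    means = sub.mean(axis=1)
    sds = sub.std(axis=1, ddof=1)
    # relative threshold: a numerically constant gene has sd at rounding level
    tol = 1e-12 * np.maximum(1.0, np.abs(means))
    zero = [g for g, s, c in zip(signature_genes, sds, tol) if s <= c]
    if zero:
        raise InputError(f"zero-variance signature gene(s): {zero}")
    Z = (sub - means[:, None]) / sds[:, None]
    cov = Z @ Z.T / (Z.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    total = float(evals.clip(min=0).sum())
    pc1, s1 = _fix_sign(evecs[:, 0])
    pc2, s2 = _fix_sign(evecs[:, 1])
    explained = (float(evals[0] / total), float(max(evals[1], 0.0) / total))
    return ScoreModel(
        list(signature_genes), means, sds, pc1, pc2, explained, (s1, s2),
        pc2_degenerate=bool(evals[1] <= 1e-10 * max(evals[0], 1.0)),
    )


def apply_score(model: ScoreModel, X) -> pd.DataFrame:
    """Score samples: standardize with training parameters, project, sum.

    Returns a DataFrame (sample_id, pc1, pc2, pca_score); pca_score is
    exactly pc1 + pc2.  Applying to the training matrix reproduces the
    training scores.
    """
    frame = _as_frame(X)
    missing = [g for g in model.signature_genes if g not in frame.index]
    if missing:
        raise InputError(f"matrix lacks signature genes: {missing}")
    sub = np.ascontiguousarray(frame.loc[model.signature_genes].to_numpy(dtype=float))
    Z = (sub - model.means[:, None]) / model.sds[:, None]
    pc1 = model.loadings_pc1 @ Z
    pc2 = model.loadings_pc2 @ Z
    return pd.DataFrame({
        "sample_id": list(frame.columns),
        "pc1": pc1,
        "pc2": pc2,
        "pca_score": pc1 + pc2,
    })


def stratify(scores: pd.DataFrame, model: ScoreModel) -> pd.DataFrame:
    """Assign low/high strata at the model cutpoint (score == cutpoint is low)."""
    if model.cutpoint is None:
        raise WritersigError("model has no cutpoint; fit one with max_rank_cutpoint")
    out = scores.copy()
    out["stratum"] = np.where(out["pca_score"] > model.cutpoint, "high", "low")
    return out
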