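"""Binary soft-margin SVM on a precomputed Gram matrix.

The optimisation is delegated to scikit-learn's SMO solver
(``SVC(kernel="precomputed")``); what this module owns is the contract: a
:class:`TrainedModel` holding the dual-form state (support instance ids,
signed dual coefficients alpha_i * y_i, bias) bound to the kernel
configuration and training-id order, with the decision function

    f(x) = sum_i dual_coefs[i] * K(x, support_i) + bias

and the documented tie rule f = 0 -> +1.  Models persist to a structured
text file and reload to bit-identical predictions.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence, TextIO

import numpy as np
from sklearn.svm import SVC

from .kernel import GramMatrix, KernelConfig

__all__ = ["TrainedModel", "train", "predict", "SingleClassError"]


class SingleClassError(ValueError):
    """Training data contained only one class."""


@dataclass
class TrainedModel:
    """Dual-form SVM state sufficient to score new kernel rows."""

    support_ids: list[str]
    dual_coefs: np.ndarray  # signed: alpha_i * y_i
    bias: float
    config: KernelConfig
    c_param: float
    training_ids: list[str]  # defines kernel-row column order

    def decision_values(self, rows: np.ndarray) -> np.ndarray:
        """f(x) for each row of kernel values against ``training_ids``."""
        rows = np.atleast_2d(np.asarray(rows, dtype=float))
        if rows.shape[1] != len(self.training_ids):
            raise ValueError(
                f"kernel rows have {rows.shape[1]} columns; "
                f"model expects {len(self.training_ids)}"
            )
        idx = [self.training_ids.index(i) for i in self.support_ids]
        return rows[:, idx] @ self.dual_coefs + self.bias

    # -- persistence -------------------------------------------------------

    def save(self, stream: TextIO) -> None:
        json.dump(
            {
                "support_ids": self.support_ids,
                "dual_coefs": [f"{v:.17g}" for v in self.dual_coefs],
                "bias": f"{self.bias:.17g}",
                "config": {
                    "variant": self.config.variant,
                    "decay": self.config.decay,
                    "normalize": self.config.normalize,
                },
                "c_param": self.c_param,
                "training_ids": self.training_ids,
            },
            stream,
            indent=1,
        )

    @classmethod
    def load(cls, stream: TextIO) -> "TrainedModel":
        blob = json.load(stream)
        return cls(
            support_ids=list(blob["support_ids"]),
            dual_coefs=np.array([float(v) for v in blob["dual_coefs"]]),
            bias=float(blob["bias"]),
            config=KernelConfig(**blob["config"]),
            c_param=float(blob["c_param"]),
            training_ids=list(blob["training_ids"]),
        )


def train(
    gram: GramMatrix,
    labels: Mapping[str, int],
    c_param: float = 1.0,
    balance_classes: bool = False,
) -> TrainedModel:
    """Fit the dual SVM on a precomputed Gram matrix.

    Parameters
    ----------
    gram:
        Kernel matrix over the training instances (every id must be labeled).
    labels:
        instance_id -> {+1, -1}; both classes must be present.
    c_param:
        Soft-margin penalty C > 0.
    balance_classes:
        If true, per-class C is scaled inversely to class frequency —
        useful for heavily skewed relation corpora; off by default.
    """
    if c_param <= 0:
        raise ValueError(f"c_param must be positive, got {c_param}")
    missing = [i for i in gram.ids if i not in labels]
    if missing:
        raise ValueError(f"unlabeled training instances: {missing[:5]}")
    y = np.array([labels[i] for i in gram.ids])
    if len(np.unique(y)) < 2:
        raise SingleClassError("cannot train one-class seed set")

    eig_floor = float(np.linalg.eigvalsh(gram.values).min())
    if eig_floor < -1e-6:
        warnings.warn(
            f"Gram matrix indefinite (min eigenvalue {eig_floor:.3g}); "
            "proceeding — the solver tolerates slight indefiniteness",
            stacklevel=2,
        )

    svc = SVC(
        C=c_param,
        kernel="precomputed",
        class_weight="balanced" if balance_classes else None,
        tol=1e-8,
        shrinking=True,
    )
    svc.fit(gram.values, y)

    support_idx = svc.support_
    return TrainedModel(
        support_ids=[gram.ids[i] for i in support_idx],
        dual_coefs=svc.dual_coef_.ravel().copy(),
        bias=float(svc.intercept_[0]),
        config=gram.config if gram.config is not None else KernelConfig(),
        c_param=float(c_param),
        training_ids=list(gram.ids),
    )


def predict(
    model: TrainedModel, rows: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Labels and signed decision values for kernel rows vs ``training_ids``.

    A decision value of exactly 0 resolves to +1 (documented tie rule).
    """
    f = model.decision_values(rows)
    labels = np.where(f >= 0.0, 1, -1)
    return labels, f
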