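"""Pluggable RE/FD classifiers.

Three backends share one contract (train on :class:`LabeledInstance`
collections, predict one label + confidence per instance):

* ``baseline`` — a deterministic lexical model: multinomial logistic
  regression over bag-of-token features of the marked text, trigger-lexicon
  counts and the inter-marker token distance. Desk-scale and fully
  reproducible under a fixed seed.
* ``oracle`` — echoes the gold label of each instance; used to validate the
  pipeline decomposition independently of any learned model.
* ``transformer-adapter`` — an optional adapter that fine-tunes a pretrained
  encoder (defaults follow the published fine-tuning configuration); it is
  only available when ``transformers``/``torch`` are installed and is never
  required by the rest of the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression

from .instances import LabeledInstance

__all__ = [
    "ClassifierConfig",
    "TransformerAdapterConfig",
    "BaselineModel",
    "OracleModel",
    "TransformerAdapter",
    "train_classifier",
    "predict_labels",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1

#: Small trigger lexicon; one count feature per category. The generator's
#: templates draw from these families, and they are common relation/function
#: cues in the real corpora too.
TRIGGER_LEXICON: dict[str, tuple[str, ...]] = {
    "up": ("increase", "increased", "increases", "enhanced", "promoted",
           "induced", "stimulated", "up-regulated", "upregulated", "augmented",
           "activated", "elevated"),
    "down": ("decrease", "decreased", "decreases", "reduced", "inhibited",
             "suppressed", "down-regulated", "downregulated", "repressed",
             "attenuated", "blocked"),
    "act": ("activity", "activation", "catalytic", "catalysis", "kinase"),
    "deg": ("degradation", "degraded", "turnover"),
    "pmod": ("phosphorylation", "phosphorylated", "modification"),
    "sec": ("secretion", "secreted", "release"),
    "tloc": ("translocation", "translocated", "trafficking"),
    "complex": ("complex", "binding", "association", "heterodimer"),
}


@dataclass(frozen=True)
class ClassifierConfig:
    """Configuration of a classifier backend.

    ``regularization`` is the inverse-strength C of the logistic model;
    ``seed`` fixes all stochastic behavior of the baseline.
    """

    backend: str = "baseline"
    label_set: tuple[str, ...] | None = None
    seed: int = 0
    regularization: float = 1.0


@dataclass(frozen=True)
class TransformerAdapterConfig:
    """Fine-tuning hyper-parameters of the optional transformer backend.

    Defaults are the published configuration for this task; every value is
    overridable. The encoder's internal representations belong to the
    pretrained model and are not re-implemented here.
    """

    batch_size: int = 4
    epochs: int = 3
    max_seq_len: int = 100
    loss: str = "categorical_crossentropy"
    learning_rate: float = 1e-5
    optimizer: str = "Adam"
    encoder_name: str = "biobert-pubmed-v1.1"


def _check_kind(instances: Sequence[LabeledInstance]) -> str:
    kinds = {inst.kind for inst in instances}
    if len(kinds) != 1:
        raise ValueError(f"instances must all be of one kind, got {sorted(kinds)}")
    return kinds.pop()


def _marker_offset(text: str, m1: str, m2: str) -> float:
    """Signed token offset from the @-marked to the $-marked entity.

    The sign carries the direction of the pair (subject before or after the
    object in text), which a bag of tokens alone cannot see; 0 for FD
    instances, which carry a single marker.
    """
    tokens = text.split()
    pos1 = [i for i, t in enumerate(tokens) if t == m1]
    pos2 = [i for i, t in enumerate(tokens) if t == m2]
    if not pos1 or not pos2:
        return 0.0
    return float(pos2[0] - pos1[0])


class BaselineModel:
    """Deterministic lexical classifier for RE or FD instances."""

    def __init__(self, config: ClassifierConfig):
        self.config = config
        self.kind: str | None = None
        self._vectorizer: CountVectorizer | None = None
        self._clf: LogisticRegression | None = None
        self._constant: str | None = None
        self.classes_: tuple[str, ...] = ()

    # -- features ----------------------------------------------------------

    def _features(self, instances: Sequence[LabeledInstance], fit: bool):
        texts = [inst.marked_text for inst in instances]
        if fit:
            self._vectorizer = CountVectorizer(
                lowercase=True, token_pattern=r"[^\s]+", ngram_range=(1, 2),
                min_df=1,
            )
            bow = self._vectorizer.fit_transform(texts)
        else:
            assert self._vectorizer is not None
            bow = self._vectorizer.transform(texts)
        extra = np.zeros((len(instances), len(TRIGGER_LEXICON) + 2))
        for i, inst in enumerate(instances):
            tokens = [t.strip(".,;()").lower() for t in inst.marked_text.split()]
            bag = set(tokens)
            for j, words in enumerate(TRIGGER_LEXICON.values()):
                extra[i, j] = sum(t in bag for t in words)
            offset = _marker_offset(inst.marked_text, "@", "$")
            extra[i, -2] = abs(offset) / 10.0
            extra[i, -1] = (0.0 if offset == 0 else (1.0 if offset > 0 else -1.0))
        return sparse.hstack([bow, sparse.csr_matrix(extra)], format="csr")

    # -- contract ----------------------------------------------------------

    def fit(self, instances: Sequence[LabeledInstance]) -> "BaselineModel":
        self.kind = _check_kind(instances)
        labels = [inst.label for inst in instances]
        classes = sorted(set(labels))
        if self.config.label_set is not None:
            unknown = set(labels) - set(self.config.label_set)
            if unknown:
                raise ValueError(f"labels outside the configured set: {unknown}")
        if len(classes) == 1:
            warnings.warn(
                f"single-class training data ({classes[0]!r}); "
                "the model will always predict that class",
                stacklevel=2,
            )
            self._constant = classes[0]
            self.classes_ = tuple(classes)
            return self
        X = self._features(instances, fit=True)
        self._clf = LogisticRegression(
            C=self.config.regularization,
            max_iter=2000,
            random_state=self.config.seed,
        )
        self._clf.fit(X, labels)
        self.classes_ = tuple(self._clf.classes_)
        return self

    def predict(
        self, instances: Sequence[LabeledInstance]
    ) -> list[tuple[str, float]]:
        if not instances:
            return []
        if _check_kind(instances) != self.kind:
            raise ValueError(
                f"model was trained for {self.kind} instances, "
                f"got {instances[0].kind}"
            )
        if self._constant is not None:
            return [(self._constant, 1.0) for _ in instances]
        assert self._clf is not None
        proba = self._clf.predict_proba(self._features(instances, fit=False))
        out = []
        for row in proba:
            k = int(np.argmax(row))
            out.append((self.classes_[k], float(row[k])))
        return out

    def predict_proba(self, instances: Sequence[LabeledInstance]) -> np.ndarray:
        if self._constant is not None:
            return np.ones((len(instances), 1))
        assert self._clf is not None
        return self._clf.predict_proba(self._features(instances, fit=False))


class OracleModel:
    """Echoes each instance's gold label; the pipeline-validation backend."""

    def __init__(self, kind: str):
        self.kind = kind

    def fit(self, instances: Sequence[LabeledInstance]) -> "OracleModel":
        return self

    def predict(
        self, instances: Sequence[LabeledInstance]
    ) -> list[tuple[str, float]]:
        if instances and _check_kind(instances) != self.kind:
            raise ValueError("instance kind does not match the model")
        return [(inst.label, 1.0) for inst in instances]


class TransformerAdapter:
    """Optional fine-tuning backend; requires ``transformers`` and ``torch``.

    The adapter consumes and produces exactly the LabeledInstance/label
    contract, so downstream evaluation cannot tell backends apart.
    """

    def __init__(self, config: TransformerAdapterConfig | None = None,
                 seed: int = 0):
        self.config = config or TransformerAdapterConfig()
        self.seed = seed
        self.kind: str | None = None

    def _require_deps(self):
        try:
            import torch  # noqa: F401
            import transformers  # noqa: F401
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "the transformer adapter requires the optional dependencies "
                "'torch' and 'transformers'"
            ) from exc
        return torch, transformers

    def fit(self, instances: Sequence[LabeledInstance]):  # pragma: no cover
        torch, transformers = self._require_deps()
        raise NotImplementedError(
            "fine-tuning is delegated to the installed transformers stack; "
            "subclass TransformerAdapter and implement fit/predict against "
            f"encoder {self.config.encoder_name!r}"
        )

    def predict(self, instances):  # pragma: no cover
        self._require_deps()
        raise NotImplementedError


def train_classifier(
    instances: Sequence[LabeledInstance], config: ClassifierConfig | None = None
):
    """Train a classifier on instances of one kind; returns the model handle."""
    config = config or ClassifierConfig()
    if config.backend == "baseline":
        return BaselineModel(config).fit(instances)
    if config.backend == "oracle":
        return OracleModel(_check_kind(instances)).fit(instances)
    if config.backend == "transformer-adapter":
        return TransformerAdapter(seed=config.seed).fit(instances)
    raise ValueError(f"unknown backend {config.backend!r}")


def predict_labels(model, instances: Sequence[LabeledInstance]):
    """One (label, confidence) per instance; confidence in [0, 1]."""
    return model.predict(list(instances))


def save_model(model, path) -> None:
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)


def load_model(path):
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model file version {payload.get('format_version')!r}"
        )
    return payload["model"]
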