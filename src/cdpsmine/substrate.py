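"""Aminoacyl-tRNA substrate prediction from pocket residues.

A categorical naive Bayes classifier maps the residue vector read off a
CDPS substrate-binding pocket to the amino acid the pocket activates.
Evaluation supports strict matching, matching relaxed to physicochemical
residue clusters, leave-one-out cross-validation, and fold enrichment over
random expectation under two configurable baseline policies.
"""

from __future__ import annotations

import csv
import json
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import yaml

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue categories seen at pocket positions: standard residues plus gap
CATEGORIES = tuple(AMINO_ACIDS) + ("-",)

#: stand-in physicochemical partition (editable; see data/physchem.yaml)
DEFAULT_PHYSCHEM = {
    "aliphatic": ["A", "V", "L", "I", "M"],
    "aromatic": ["F", "W", "Y"],
    "polar": ["S", "T", "N", "Q"],
    "acidic": ["D", "E"],
    "basic": ["K", "R", "H"],
    "cysteine": ["C"],
    "glycine": ["G"],
    "proline": ["P"],
}


@dataclass
class TrainingSet:
    """Labeled examples for one pocket: (residue vector, substrate label)."""

    site: str  # {P1, P2}
    examples: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.site not in ("P1", "P2", "pooled"):
            raise ValueError(f"site must be P1/P2/pooled, got {self.site!r}")
        lengths = {len(v) for v, _ in self.examples}
        if len(lengths) > 1:
            raise ValueError(f"inconsistent residue vector lengths: {sorted(lengths)}")
        for _, label in self.examples:
            if label not in AMINO_ACIDS:
                raise ValueError(f"label {label!r} is not a standard amino acid")

    @property
    def n_positions(self) -> int:
        return len(self.examples[0][0]) if self.examples else 0

    @classmethod
    def from_tsv(cls, path: str | Path, site: str) -> "TrainingSet":
        """Load rows (site, residues, label) from TSV, keeping the given site."""
        examples = []
        with open(path) as fh:
            reader = csv.reader(fh, delimiter="\t")
            header = next(reader)
            for row in reader:
                rec = dict(zip(header, row))
                if rec["site"] == site or site == "pooled":
                    examples.append((rec["residues"], rec["label"]))
        return cls(site=site, examples=examples)


@dataclass
class PhysChemClusters:
    """A partition of the 20 standard amino acids into named groups."""

    groups: dict[str, list[str]]

    def __post_init__(self) -> None:
        members = [aa for g in self.groups.values() for aa in g]
        if sorted(members) != sorted(AMINO_ACIDS):
            raise ValueError("groups must partition the 20 standard amino acids")
        self._group_of = {aa: name for name, g in self.groups.items() for aa in g}

    def group_of(self, aa: str) -> str:
        return self._group_of[aa]

    @classmethod
    def default(cls) -> "PhysChemClusters":
        return cls({k: list(v) for k, v in DEFAULT_PHYSCHEM.items()})

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysChemClusters":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))


@dataclass
class NaiveBayesModel:
    site: str
    classes: list[str]
    priors: dict[str, float]
    # likelihoods[position][class][category] -> probability
    likelihoods: list[dict[str, dict[str, float]]]
    smoothing_alpha: float

    def __post_init__(self) -> None:
        if abs(sum(self.priors.values()) - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        for pos in self.likelihoods:
            for cls_name, dist in pos.items():
                if abs(sum(dist.values()) - 1.0) > 1e-9:
                    raise ValueError(f"likelihoods for {cls_name} must sum to 1")

    def to_dict(self) -> dict:
        return {
            "site": self.site,
            "classes": self.classes,
            "priors": self.priors,
            "likelihoods": self.likelihoods,
            "smoothing_alpha": self.smoothing_alpha,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NaiveBayesModel":
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "NaiveBayesModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SubstratePrediction:
    site: str
    label: str
    posterior: float
    ranking: list[tuple[str, float]] = field(default_factory=list)


def train(training: TrainingSet, alpha: float = 1.0) -> NaiveBayesModel:
    """Fit the classifier: class-frequency priors, Laplace-smoothed
    per-position categorical likelihoods ('-' is a residue category)."""
    if not training.examples:
        raise ValueError("training set is empty")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    labels = [label for _, label in training.examples]
    n = len(labels)
    class_counts = Counter(labels)
    classes = sorted(class_counts)
    priors = {c: class_counts[c] / n for c in classes}
    n_cat = len(CATEGORIES)
    likelihoods: list[dict[str, dict[str, float]]] = []
    for pos in range(training.n_positions):
        per_class: dict[str, dict[str, float]] = {}
        for c in classes:
            counts = Counter(
                vec[pos] for vec, label in training.examples if label == c
            )
            total = class_counts[c] + alpha * n_cat
            per_class[c] = {
                cat: (counts.get(cat, 0) + alpha) / total for cat in CATEGORIES
            }
        likelihoods.append(per_class)
    return NaiveBayesModel(
        site=training.site,
        classes=classes,
        priors=priors,
        likelihoods=likelihoods,
        smoothing_alpha=alpha,
    )


def predict(model: NaiveBayesModel, vector: str) -> SubstratePrediction:
    """Posterior over substrate classes for a pocket residue vector.

    Computed in log space; categories unseen in training never zero the
    posterior thanks to smoothing. Ties break alphabetically.
    """
    if len(vector) != len(model.likelihoods):
        raise ValueError(
            f"vector length {len(vector)} != model positions {len(model.likelihoods)}"
        )
    log_post = {}
    for c in model.classes:
        lp = math.log(model.priors[c])
        for pos, cat in enumerate(vector):
            dist = model.likelihoods[pos][c]
            # residues outside the category set (e.g. X) carry no signal
            if cat in dist:
                lp += math.log(dist[cat])
        log_post[c] = lp
    m = max(log_post.values())
    unnorm = {c: math.exp(v - m) for c, v in log_post.items()}
    z = sum(unnorm.values())
    posteriors = {c: v / z for c, v in unnorm.items()}
    ranking = sorted(posteriors.items(), key=lambda kv: (-kv[1], kv[0]))
    label, post = ranking[0]
    return SubstratePrediction(site=model.site, label=label, posterior=post, ranking=ranking)


def relaxed_match(predicted: str, true: str, clusters: PhysChemClusters) -> bool:
    """True iff the labels are equal or fall in the same physicochemical group."""
    if predicted not in AMINO_ACIDS or true not in AMINO_ACIDS:
        raise ValueError("labels must be standard amino acids")
    return predicted == true or clusters.group_of(predicted) == clusters.group_of(true)


def loocv(
    training: TrainingSet,
    clusters: PhysChemClusters | None = None,
    alpha: float = 1.0,
) -> dict:
    """Leave-one-out cross-validation.

    Returns strict and cluster-relaxed accuracies plus a per-class
    confusion table {true -> {predicted -> count}}.
    """
    if len(training.examples) < 2:
        raise ValueError("need at least 2 examples for LOOCV")
    clusters = clusters or PhysChemClusters.default()
    strict = relaxed = 0
    confusion: dict[str, Counter] = {}
    n = len(training.examples)
    for i, (vec, true_label) in enumerate(training.examples):
        rest = TrainingSet(
            site=training.site,
            examples=training.examples[:i] + training.examples[i + 1 :],
        )
        model = train(rest, alpha=alpha)
        pred = predict(model, vec).label
        confusion.setdefault(true_label, Counter())[pred] += 1
        if pred == true_label:
            strict += 1
        if relaxed_match(pred, true_label, clusters):
            relaxed += 1
    return {
        "strict_accuracy": strict / n,
        "relaxed_accuracy": relaxed / n,
        "confusion": {t: dict(c) for t, c in confusion.items()},
        "n": n,
    }


def overall_accuracy(p1_relaxed: float, p2_relaxed: float) -> float:
    """Overall substrate accuracy: arithmetic mean of the two per-site
    accuracies (in percent), rounded to one decimal for reporting."""
    for v in (p1_relaxed, p2_relaxed):
        if not 0.0 <= v <= 100.0:
            raise ValueError("accuracies must be in [0, 100]")
    mean = (p1_relaxed + p2_relaxed) / 2.0
    return math.floor(mean * 10 + 0.5) / 10


def enrichment(accuracy: float, baseline: float) -> float:
    """Fold enrichment of an accuracy over a random baseline."""
    if baseline <= 0:
        raise ValueError("baseline must be > 0")
    return accuracy / baseline


def random_baselines(training: TrainingSet) -> dict[str, float]:
    """The two candidate definitions of random expectation.

    uniform: 1/K over the K observed classes;
    prior_matched: sum of squared class priors (accuracy of a predictor
    drawing labels from the empirical class distribution).
    """
    labels = [label for _, label in training.examples]
    counts = Counter(labels)
    k = len(counts)
    n = len(labels)
    return {
        "uniform": 1.0 / k,
        "prior_matched": sum((c / n) ** 2 for c in counts.values()),
    }
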