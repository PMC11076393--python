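"""Feature discretization to natural language and report generation.

The six headline pair features are discretized into up to five
equal-frequency bins fitted on the candidate-set distribution; each bin
carries an ordered natural-language label ("Very similar" … "Very
dissimilar").  The labels, the model score and rank, and a one-line glossary
per feature are assembled into a deterministic retrieval-augmented prompt.
A pluggable LLM client may turn the prompt into free text; the default
offline renderer produces a structured report with no network access.

Note the embedding feature is a *distance*: small values mean similar genes,
so its label order runs from "Very similar" at the low end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .types import GenePair

logger = logging.getLogger("bspai")

MAX_BINS = 5

#: ordered label vocabularies, low feature value first
DEFAULT_VOCABULARIES: dict[str, list[str]] = {
    "embedding_distance": [
        "Very similar",
        "Somewhat similar",
        "Similar",
        "Dissimilar",
        "Very dissimilar",
    ],
    "safety_score": [
        "Unsafe",
        "Moderately low safety",
        "Safe",
        "Moderately high safety",
        "High safety",
    ],
    "pearson_r": [
        "Strongly negative correlation",
        "Weakly negative correlation",
        "Uncorrelated",
        "Weakly positive correlation",
        "Strongly positive correlation",
    ],
    "single_ratio_max": ["Low", "Moderately low", "Moderate", "Moderately high", "High"],
    "double_ratio_max": ["Low", "Moderately low", "Moderate", "Moderately high", "High"],
    "cooccurrence_count": [
        "No shared pathways",
        "Few shared pathways",
        "Some shared pathways",
        "Many shared pathways",
        "Very many shared pathways",
    ],
}

GENERIC_VOCABULARY = ["Very low", "Low", "Moderate", "High", "Very high"]

#: the six headline features passed to the language stage
HEADLINE_FEATURES = (
    "embedding_distance",
    "safety_score",
    "pearson_r",
    "single_ratio_max",
    "double_ratio_max",
    "cooccurrence_count",
)

FEATURE_GLOSSARY: dict[str, str] = {
    "embedding_distance": (
        "Euclidean distance between the two genes' co-expression embedding vectors; "
        "smaller means the genes behave more similarly"
    ),
    "safety_score": (
        "quasi-harmonic mean of each gene's tumor-minus-normal mean expression "
        "difference; higher means more tumor-restricted expression, hence safer"
    ),
    "pearson_r": (
        "Pearson correlation of the two genes' expression across single cells; "
        "positive values indicate co-expression"
    ),
    "single_ratio_max": (
        "largest fraction of cells, in either gene's top-expressing populations, "
        "with that single gene above the expression threshold"
    ),
    "double_ratio_max": (
        "largest fraction of cells in which both genes are simultaneously above "
        "the expression threshold, over the evaluated populations"
    ),
    "cooccurrence_count": "number of annotated biological pathways containing both genes",
}

DIRECTION_NOTES: dict[str, str] = {
    "embedding_distance": "distance: low value = very similar genes",
    "safety_score": "higher = safer",
    "pearson_r": "sign gives direction of co-expression",
    "single_ratio_max": "higher = more active single target",
    "double_ratio_max": "higher = more double-positive cells",
    "cooccurrence_count": "higher = more shared pathways",
}


# ---------------------------------------------------------------------------
# binning


@dataclass
class BinEntry:
    """Equal-frequency bins for one feature.

    ``edges`` are the k-1 strictly increasing internal cut points defining k
    left-open intervals covering the whole real line (outer intervals are
    unbounded); ``labels`` has exactly k ordered entries.
    """

    edges: list[float]
    labels: list[str]
    direction_note: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.edges) + 1:
            raise ValueError("need exactly one label per interval")
        if len(self.labels) > MAX_BINS:
            raise ValueError(f"at most {MAX_BINS} bins are supported")
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly increasing")

    def label_for(self, value: float) -> str:
        """Label of the left-open interval (edge_{i-1}, edge_i] containing value."""
        idx = int(np.searchsorted(np.asarray(self.edges), value, side="left"))
        return self.labels[idx]


@dataclass
class BinningScheme:
    """Per-feature equal-frequency bin entries, JSON-serializable bit-exactly."""

    entries: dict[str, BinEntry] = field(default_factory=dict)

    def __contains__(self, feature: str) -> bool:
        return feature in self.entries

    def __getitem__(self, feature: str) -> BinEntry:
        return self.entries[feature]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            feat: {
                "edges": [repr(float(e)) for e in entry.edges],
                "labels": entry.labels,
                "direction_note": entry.direction_note,
            }
            for feat, entry in self.entries.items()
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BinningScheme":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        entries = {
            feat: BinEntry(
                edges=[float(e) for e in spec["edges"]],
                labels=list(spec["labels"]),
                direction_note=spec.get("direction_note", ""),
            )
            for feat, spec in payload.items()
        }
        return cls(entries)


def fit_equal_frequency_bins(
    values: Sequence[float], n_bins: int, labels: Sequence[str], direction_note: str = ""
) -> BinEntry:
    """Quantile cut points at i/n_bins; duplicate edges merged.

    With heavy ties fewer than ``n_bins`` intervals survive and the label
    list is truncated from the extremes inward (a constant feature keeps
    only the middle label, with a warning).
    """
    if not (1 <= n_bins <= MAX_BINS):
        raise ValueError(f"n_bins must be in 1..{MAX_BINS}")
    labels = list(labels)
    if len(labels) != n_bins:
        raise ValueError("need one label per requested bin")
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no finite values to bin")
    qs = np.arange(1, n_bins) / n_bins
    edges = np.unique(np.quantile(arr, qs))
    # intervals are left-open: an edge >= max or < min would leave an empty
    # unbounded outer interval, so such cut points are dropped
    edges = edges[(edges >= arr.min()) & (edges < arr.max())]
    k = len(edges) + 1
    if k == 1:
        logger.warning("constant feature; single bin labeled %r", labels[n_bins // 2])
    start = (n_bins - k) // 2
    return BinEntry(edges=[float(e) for e in edges], labels=labels[start : start + k],
                    direction_note=direction_note)


def discretize_to_language(value: float, scheme: BinningScheme, feature: str) -> str:
    """Natural-language label of ``value`` under the fitted scheme."""
    if feature not in scheme:
        raise KeyError(f"no fitted bins for feature {feature!r}")
    return scheme[feature].label_for(value)


class EqualFrequencyBinner(BaseEstimator, TransformerMixin):
    """Fit per-feature equal-frequency bins on a candidate feature table.

    Parameters
    ----------
    n_bins : int, default 5
        Requested bins per feature (at most 5; ties may reduce this).
    features : sequence of str or None
        Columns to bin; None means the six headline features present.
    vocabularies : mapping feature -> ordered labels, optional
        Overrides merged over the built-in vocabularies.

    Attributes
    ----------
    scheme_ : BinningScheme
    """

    def __init__(
        self,
        n_bins: int = 5,
        features: Sequence[str] | None = None,
        vocabularies: dict[str, list[str]] | None = None,
    ):
        self.n_bins = n_bins
        self.features = features
        self.vocabularies = vocabularies

    def fit(self, X: pd.DataFrame, y=None) -> "EqualFrequencyBinner":
        vocab = {**DEFAULT_VOCABULARIES, **(self.vocabularies or {})}
        feats = self.features
        if feats is None:
            feats = [f for f in HEADLINE_FEATURES if f in X.columns]
        missing = [f for f in feats if f not in X.columns]
        if missing:
            raise ValueError(f"features absent from table: {missing}")
        entries = {}
        for feat in feats:
            labels = vocab.get(feat, GENERIC_VOCABULARY)[: self.n_bins]
            entries[feat] = fit_equal_frequency_bins(
                X[feat].to_numpy(), self.n_bins, labels, DIRECTION_NOTES.get(feat, "")
            )
        self.scheme_ = BinningScheme(entries)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        feats = list(self.scheme_.entries)
        out = {
            feat: [self.scheme_[feat].label_for(v) for v in X[feat].to_numpy()]
            for feat in feats
        }
        return pd.DataFrame(out, index=X.index)


# ---------------------------------------------------------------------------
# prompt assembly and report rendering


@dataclass
class PromptBundle:
    """Everything retrieved for one pair's report."""

    pair: GenePair
    nl_features: dict[str, str]
    score: float
    rank: int
    n_candidates: int
    feature_glossary: dict[str, str] = field(default_factory=lambda: dict(FEATURE_GLOSSARY))
    template_id: str = "offline-v1"

    def __post_init__(self) -> None:
        missing = [f for f in self.nl_features if f not in self.feature_glossary]
        if missing:
            raise ValueError(f"no glossary entry for features {missing}")


def make_bundle(
    pair: GenePair,
    feature_row: pd.Series,
    scheme: BinningScheme,
    score: float,
    rank: int,
    n_candidates: int,
    headline_features: Iterable[str] = HEADLINE_FEATURES,
) -> PromptBundle:
    """Discretize one pair's headline features and package them for prompting."""
    nl = {
        feat: discretize_to_language(float(feature_row[feat]), scheme, feat)
        for feat in headline_features
        if feat in scheme
    }
    return PromptBundle(pair=pair, nl_features=nl, score=score, rank=rank,
                        n_candidates=n_candidates)


def assemble_prompt(bundle: PromptBundle) -> str:
    """Deterministic retrieval-augmented prompt text for one target pair."""
    a, b = bundle.pair.gene_a, bundle.pair.gene_b
    lines = [
        f"You are assisting the design of a bispecific antibody targeting {a} and {b}.",
        "",
        "Machine learning evidence retrieved for this target pair:",
    ]
    for feat, label in bundle.nl_features.items():
        gloss = bundle.feature_glossary[feat]
        lines.append(f"- {feat}: {label} ({gloss}).")
    lines += [
        f"- Model prediction score: {bundle.score:.2f}. "
        f"Ranked {bundle.rank} out of {bundle.n_candidates:,} candidates.",
        "",
        "Instructions:",
        f"1. Summarize the clinical progress of antibodies against {a}.",
        f"2. Summarize the clinical progress of antibodies against {b}.",
        "3. Discuss the machine learning evidence above, feature by feature, and what "
        "each label implies for combining the two targets in one bispecific antibody.",
        "4. Conclude whether the combination is promising, naming both supporting "
        "evidence and open risks.",
    ]
    return "\n".join(lines)


class LLMClient(Protocol):
    """Pluggable large-language-model interface."""

    def complete(self, prompt: str) -> str:  # pragma: no cover - protocol
        ...


@dataclass
class Report:
    pair: GenePair
    body: str
    prompt: str
    provenance: dict


def _offline_body(bundle: PromptBundle) -> str:
    a, b = bundle.pair.gene_a, bundle.pair.gene_b
    sections = [
        f"# Bispecific target analysis: {a} + {b}",
        "",
        f"## {a}",
        f"Clinical progress: consult the latest literature and trial registries for {a}; "
        "this offline report carries no external retrieval.",
        "",
        f"## {b}",
        f"Clinical progress: consult the latest literature and trial registries for {b}; "
        "this offline report carries no external retrieval.",
        "",
        "## Machine learning model analysis",
    ]
    for feat, label in bundle.nl_features.items():
        sections.append(f"- {feat}: {label}. {bundle.feature_glossary[feat]}.")
    sections += [
        f"- Machine learning model prediction score: {bundle.score:.2f}. "
        f"Ranked {bundle.rank} out of {bundle.n_candidates:,} candidates.",
        "",
        "## Conclusion",
        f"The combination of {a} and {b} scores {bundle.score:.2f}, placing it at rank "
        f"{bundle.rank} of {bundle.n_candidates:,} evaluated candidate pairs. "
        "The discretized features above summarize the model's evidence; review the "
        "per-feature labels (in particular safety and co-expression) against current "
        "clinical knowledge before advancing this pair.",
    ]
    return "\n".join(sections)


def render_report(bundle: PromptBundle, client: LLMClient | None = None) -> Report:
    """Render the analysis report.

    With no client the offline template produces a structured report from
    the bundle alone.  A configured client receives the assembled prompt
    verbatim; on client failure the offline fallback is used and flagged in
    the provenance metadata.
    """
    prompt = assemble_prompt(bundle)
    if client is None:
        return Report(bundle.pair, _offline_body(bundle), prompt,
                      {"renderer": "offline-template", "template_id": bundle.template_id})
    try:
        body = client.complete(prompt)
        prov = {"renderer": type(client).__name__, "template_id": bundle.template_id}
    except Exception as exc:  # noqa: BLE001 - any client failure falls back
        logger.warning("LLM client failed (%s); falling back to offline template", exc)
        body = _offline_body(bundle)
        prov = {
            "renderer": "offline-template",
            "template_id": bundle.template_id,
            "client_error": str(exc),
        }
    return Report(bundle.pair, body, prompt, prov)
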