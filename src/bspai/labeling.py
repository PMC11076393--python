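"""Clinical-progress labels and ranking supervision.

Drugs carry a 5-level ordinal clinical-progress code (1 = Approved/NDA/BLA,
2 = Phase 3 or 2/3, 3 = Phase 1 or 2, 4 = Preclinical/IND, 5 =
Discontinued/pending; smaller = more advanced).  Pairs inherit the most
advanced stage over their drugs; ordinal stages induce preference pairs
(winner more advanced than loser) for learning-to-rank objectives.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .types import DrugRecord, GenePair, PairLabel, PreferencePair

logger = logging.getLogger("bspai")

#: canonical stage vocabulary, one representative string per code
STAGE_VOCABULARY: dict[int, str] = {
    1: "Approved, NDA/BLA",
    2: "Phase 3, 2/3",
    3: "Phase 1, 2",
    4: "Preclinical, IND application",
    5: "Discontinued/pending",
}


def parse_stage(stage_text: str) -> int:
    """Map free clinical-progress text onto the 5-level ordinal code.

    Keyword matching is case-insensitive: approval/NDA/BLA -> 1;
    discontinued or pending -> 5; preclinical or IND -> 4; phase strings
    mentioning phase 3 (incl. 2/3) -> 2; other phase 1/2 strings -> 3.
    """
    if not stage_text or not stage_text.strip():
        raise ValueError("empty clinical-progress text")
    text = stage_text.strip().lower()
    if "approved" in text or "nda" in text or "bla" in text:
        return 1
    if "discontinued" in text or "pending" in text:
        return 5
    if "preclinical" in text or re.search(r"\bind\b", text):
        return 4
    if "phase" in text:
        if "3" in text:
            return 2
        if "1" in text or "2" in text:
            return 3
    raise ValueError(f"unrecognized clinical-progress text {stage_text!r}")


def aggregate_pair_labels(
    records: Sequence[DrugRecord], positive_stages: Sequence[int] = (1,)
) -> list[PairLabel]:
    """One label per distinct pair: best (minimum) stage over its drugs.

    ``positive_stages`` sets the binary positive class (default: approved
    drugs only).  Output is sorted by canonical pair for order invariance.
    """
    if not records:
        raise ValueError("no drug records to aggregate")
    # one record per drug_id: on conflict keep the most advanced (smallest code)
    by_drug: dict[str, DrugRecord] = {}
    n_conflicts = 0
    for rec in records:
        prev = by_drug.get(rec.drug_id)
        if prev is None:
            by_drug[rec.drug_id] = rec
        elif prev.pair != rec.pair or prev.stage_code != rec.stage_code:
            n_conflicts += 1
            if rec.stage_code < prev.stage_code:
                by_drug[rec.drug_id] = rec
    if n_conflicts:
        logger.warning("kept most advanced record for %d conflicting drug ids", n_conflicts)
    by_pair: dict[GenePair, list[DrugRecord]] = {}
    for rec in by_drug.values():
        by_pair.setdefault(rec.pair, []).append(rec)
    labels = []
    for pair in sorted(by_pair):
        recs = by_pair[pair]
        best = min(r.stage_code for r in recs)
        labels.append(
            PairLabel(
                pair=pair,
                best_stage=best,
                binary=int(best in positive_stages),
                n_drugs=len(recs),
            )
        )
    return labels


def make_preference_pairs(
    labels: Sequence[PairLabel],
    max_pairs: int | None = None,
    seed: int = 0,
) -> list[PreferencePair]:
    """All (winner, loser) combinations across distinct stages.

    The winner's stage code is strictly smaller (more advanced).  When
    ``max_pairs`` is given the full list is subsampled deterministically.
    """
    prefs: list[PreferencePair] = []
    ordered = sorted(labels, key=lambda lab: (lab.best_stage, lab.pair))
    for i, win in enumerate(ordered):
        for lose in ordered[i + 1 :]:
            if win.best_stage < lose.best_stage:
                prefs.append(PreferencePair(win.pair, lose.pair))
    if not prefs:
        logger.warning("all %d labels share one stage; no preference pairs", len(labels))
        return []
    if max_pairs is not None and len(prefs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(prefs), size=max_pairs, replace=False))
        prefs = [prefs[i] for i in idx]
    return prefs


@dataclass
class PairDataset:
    """Row-aligned design matrix with ordinal + binary targets and CV folds."""

    X: pd.DataFrame  # index = pair string, columns = feature names
    pairs: list[GenePair]
    stage: np.ndarray  # ordinal stage codes, 1..5
    y: np.ndarray  # binary labels
    folds: np.ndarray  # fold id per row, 0..cv_folds-1
    n_folds: int
    seed: int
    candidates: pd.DataFrame | None = None  # unlabeled pairs: scored, never trained on

    @property
    def relevance(self) -> np.ndarray:
        """Ranking gain: higher for more advanced stages (6 - stage_code)."""
        return 6 - self.stage

    def feature_names(self) -> list[str]:
        return list(self.X.columns)


def build_dataset(
    labels: Sequence[PairLabel],
    feature_table: pd.DataFrame,
    cv_folds: int = 5,
    seed: int = 0,
    candidates: pd.DataFrame | None = None,
) -> PairDataset:
    """Align labeled pairs with their feature rows and assign stratified folds.

    ``feature_table`` is indexed by the canonical pair string.  Every labeled
    pair must have a feature row; unlabeled candidate rows may be carried
    alongside for scoring but are never used in training.
    """
    labels = sorted(labels, key=lambda lab: lab.pair)
    keys = [str(lab.pair) for lab in labels]
    missing = [k for k in keys if k not in feature_table.index]
    if missing:
        raise ValueError(f"labeled pairs missing feature rows: {missing[:10]}")
    X = feature_table.loc[keys].copy()
    stage = np.array([lab.best_stage for lab in labels], dtype=int)
    y = np.array([lab.binary for lab in labels], dtype=int)

    folds = np.zeros(len(labels), dtype=int)
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    strat = y if len(np.unique(y)) > 1 else stage
    for f, (_, test_idx) in enumerate(skf.split(X, strat)):
        folds[test_idx] = f
    return PairDataset(
        X=X,
        pairs=[lab.pair for lab in labels],
        stage=stage,
        y=y,
        folds=folds,
        n_folds=cv_folds,
        seed=seed,
        candidates=candidates,
    )


def write_labels(labels: Sequence[PairLabel], path) -> None:
    pd.DataFrame(
        {
            "pair": [str(lab.pair) for lab in labels],
            "best_stage": [lab.best_stage for lab in labels],
            "binary": [lab.binary for lab in labels],
            "n_drugs": [lab.n_drugs for lab in labels],
        }
    ).to_csv(path, sep="\t", index=False)


def write_preference_pairs(prefs: Sequence[PreferencePair], path) -> None:
    pd.DataFrame(
        {
            "winner": [str(p.winner) for p in prefs],
            "loser": [str(p.loser) for p in prefs],
        }
    ).to_csv(path, sep="\t", index=False)
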