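"""Bioactivity-score aggregation and the two-stage selection cascade.

The screening workflow ranks candidates by a "final" bioactivity score: the
maximum of the six per-target-class scores (GPCR ligand, ion-channel
modulator, kinase inhibitor, nuclear-receptor ligand, protease inhibitor,
other enzyme inhibitor) plus their arithmetic mean. Selection proceeds in
two reductions — compounds with a positive lead-likeness flag
(sub-collection 1), then those with a strictly positive final score
(sub-collection 2) — and the "most perspective" set is the intersection of
the top-k by final bioactivity score and the top-k by overall drug score
within sub-collection 2.

"Positive" is read as strictly greater than zero; a final score of exactly
zero is excluded (no roster member prints one, so the choice is benign).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional

import pandas as pd

from .config import DEFAULT_CONFIG, DrugScoreModel
from .registry import BIOACTIVITY_COLUMNS, TOXICITY_COLUMNS

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BioactivityScores:
    """Six category scores with their max/avg/final aggregation."""
    gpcrl: float
    ichm: float
    ki: float
    nrl: float
    pi: float
    ei: float
    max_score: float
    avg_score: float
    final_score: float


def final_bioactivity_score(scores: Mapping[str, float]) -> BioactivityScores:
    """Aggregate the six category scores: final = max + mean.

    Computation is at full precision; round only for reporting. Missing or
    non-finite categories raise, naming the column.
    """
    vals = []
    for col in BIOACTIVITY_COLUMNS:
        if col not in scores:
            raise ValueError(f"missing bioactivity category {col!r}")
        v = float(scores[col])
        if not math.isfinite(v):
            raise ValueError(f"non-finite bioactivity score in column {col!r}")
        vals.append(v)
    mx = max(vals)
    avg = sum(vals) / len(vals)
    return BioactivityScores(
        gpcrl=vals[0], ichm=vals[1], ki=vals[2], nrl=vals[3], pi=vals[4],
        ei=vals[5], max_score=mx, avg_score=avg, final_score=mx + avg)


@dataclass(frozen=True)
class ToxicityProfile:
    """Semaphore levels for the four toxicity endpoints."""
    mutagenic: str = "none"
    tumorigenic: str = "none"
    irritant: str = "none"
    reproductive: str = "none"

    def __post_init__(self):
        for name, lvl in asdict(self).items():
            if lvl not in ("none", "medium", "high"):
                raise ValueError(f"toxicity endpoint {name}: bad level {lvl!r}")


def osiris_drug_score(druglikeness: float, clogp: float, logs: float,
                      mw: float, toxicity: ToxicityProfile,
                      model: DrugScoreModel | None = None) -> float:
    """Overall drug score in (0, 1].

    Product of per-property desirabilities 0.5 + 0.5/(1 + exp(a*p + b))
    over drug-likeness, cLogP, logS and MW, times one multiplier per
    toxicity endpoint ({none, medium, high} -> {1.0, 0.8, 0.6}). Degrading
    any toxicity level can therefore never increase the score.
    """
    m = model or DEFAULT_CONFIG.drug_score
    for name, v in (("druglikeness", druglikeness), ("clogp", clogp),
                    ("logs", logs), ("mw", mw)):
        if v is None or not math.isfinite(float(v)):
            raise ValueError(f"missing drug-score component {name!r}")

    def desir(value: float, ab: tuple[float, float]) -> float:
        a, b = ab
        return 0.5 + 0.5 / (1.0 + math.exp(a * value + b))

    score = (desir(clogp, m.clogp_ab)
             * desir(logs, m.logs_ab)
             * desir(mw, m.mw_ab)
             * desir(druglikeness, m.druglikeness_ab))
    for level in (toxicity.mutagenic, toxicity.tumorigenic,
                  toxicity.irritant, toxicity.reproductive):
        score *= m.toxicity_multipliers[level]
    return score


# ---------------------------------------------------------------------------
# the cascade
# ---------------------------------------------------------------------------

@dataclass
class CascadeResult:
    sub1_codes: set[str] = field(default_factory=set)
    sub2_codes: set[str] = field(default_factory=set)
    top_bioactivity: list[str] = field(default_factory=list)
    top_drugscore: list[str] = field(default_factory=list)
    perspective_set: set[str] = field(default_factory=set)
    final_scores: dict[str, float] = field(default_factory=dict)
    drug_scores: dict[str, float] = field(default_factory=dict)
    standards: set[str] = field(default_factory=set)

    def to_json_dict(self) -> dict:
        return {
            "sub1_codes": sorted(self.sub1_codes),
            "sub2_codes": sorted(self.sub2_codes),
            "top_bioactivity": list(self.top_bioactivity),
            "top_drugscore": list(self.top_drugscore),
            "perspective_set": sorted(self.perspective_set),
            "standards": sorted(self.standards),
            "final_scores": {k: round(v, 4)
                             for k, v in sorted(self.final_scores.items())},
            "drug_scores": {k: round(v, 4)
                            for k, v in sorted(self.drug_scores.items())},
        }


def subcollection1(codes: Iterable[str],
                   leadlike_flags: Mapping[str, str]) -> set[str]:
    """Codes with a positive ('Y') lead-likeness flag."""
    out = set()
    for code in codes:
        if code not in leadlike_flags:
            raise ValueError(f"missing lead-likeness flag for {code!r}")
        if str(leadlike_flags[code]).strip().upper() == "Y":
            out.add(code)
    return out


def subcollection2(sub1: Iterable[str],
                   final_scores: Mapping[str, float]) -> set[str]:
    """Sub-collection-1 codes with a strictly positive final score."""
    out = set()
    for code in sub1:
        if code not in final_scores:
            raise ValueError(f"missing final bioactivity score for {code!r}")
        if final_scores[code] > 0.0:
            out.add(code)
    return out


def _topk(codes: set[str], scores: Mapping[str, float], k: int) -> list[str]:
    # descending score, ties broken by code ascending (and logged)
    ordered = sorted(codes, key=lambda c: (-scores[c], c))
    if len(ordered) > k:
        boundary = scores[ordered[k - 1]]
        if any(scores[c] == boundary for c in ordered[k:]):
            logger.warning("tie at rank %d (score %.4f); broken by code order",
                           k, boundary)
    return ordered[:k]


def perspective_intersection(sub2: set[str],
                             final_scores: Mapping[str, float],
                             drug_scores: Mapping[str, float],
                             k: int = 3) -> CascadeResult:
    """Top-k rankings by final bioactivity and by drug score, and their
    intersection (order-invariant with deterministic tie-breaks)."""
    for code in sub2:
        if code not in final_scores:
            raise ValueError(f"missing final score for {code!r}")
        if code not in drug_scores:
            raise ValueError(f"missing drug score for {code!r}")
    if k > len(sub2):
        logger.warning("k=%d exceeds |sub2|=%d; clamping", k, len(sub2))
        k = len(sub2)
    top_bio = _topk(sub2, final_scores, k)
    top_ds = _topk(sub2, drug_scores, k)
    return CascadeResult(
        sub2_codes=set(sub2),
        top_bioactivity=top_bio,
        top_drugscore=top_ds,
        perspective_set=set(top_bio) & set(top_ds),
        final_scores={c: final_scores[c] for c in sub2},
        drug_scores={c: drug_scores[c] for c in sub2},
    )


def double_plot_data(codes: Iterable[str],
                     final_scores: Mapping[str, float],
                     drug_scores: Mapping[str, float],
                     standards: Iterable[str] = ()) -> pd.DataFrame:
    """Per-compound (drug score, final bioactivity score) table in
    deterministic (code-sorted) order; reference standards are appended and
    flagged rather than mixed into the selection."""
    standards = set(standards)
    rows = [{"code": c, "drug_score": drug_scores[c],
             "final_score": final_scores[c], "standard": False}
            for c in sorted(set(codes) - standards)]
    rows += [{"code": c, "drug_score": drug_scores[c],
              "final_score": final_scores[c], "standard": True}
             for c in sorted(standards)]
    return pd.DataFrame(rows, columns=["code", "drug_score", "final_score",
                                       "standard"])


def run_cascade(score_table: pd.DataFrame, k: int = 3,
                standards: Iterable[str] = (),
                codes: Optional[Iterable[str]] = None) -> CascadeResult:
    """Full cascade over a score table (real transcription or synthetic).

    ``score_table`` must be indexed by code and carry the six bioactivity
    columns, a ``leadlikeness`` flag column and a ``drug_score`` column.
    ``codes`` restricts the roster (default: every table row).
    """
    for col in (*BIOACTIVITY_COLUMNS, "leadlikeness", "drug_score"):
        if col not in score_table.columns:
            raise ValueError(f"score table missing column {col!r}")
    codes = list(codes) if codes is not None else list(score_table.index)
    missing = [c for c in codes if c not in score_table.index]
    if missing:
        raise ValueError(f"score table missing rows for {missing}")
    finals = {c: final_bioactivity_score(score_table.loc[c]).final_score
              for c in codes}
    drug_scores = {c: float(score_table.loc[c, "drug_score"]) for c in codes}
    flags = {c: str(score_table.loc[c, "leadlikeness"]) for c in codes}
    sub1 = subcollection1(codes, flags)
    sub2 = subcollection2(sub1, finals)
    result = perspective_intersection(sub2, finals, drug_scores, k=k)
    result.sub1_codes = sub1
    result.standards = set(standards) & set(codes)
    result.final_scores = finals
    result.drug_scores = drug_scores
    return result


def toxicity_profile_from_row(row: Mapping[str, str]) -> ToxicityProfile:
    """Build a :class:`ToxicityProfile` from score-table columns."""
    vals = {}
    for col in TOXICITY_COLUMNS:
        vals[col.removeprefix("tox_")] = str(row.get(col, "none"))
    return ToxicityProfile(**vals)
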