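"""Log-score classification of unknown spectra against an MSP library.

The score is the widely described three-component composite on the 0-3
scale: the fraction of query peaks matched to the reference, the fraction
of reference peaks matched (optionally weighted by MSP peak frequency), and
the agreement of matched-peak intensity patterns; the final score is
log10(1000 x product), clamped to [0, 3].  A perfect match scores 3.0.

Species calls follow a replicate-consensus rubric: an isolate is identified
at the species level when at least ``min_replicates`` of its replicates
place the same library entry first with a log score at or above the
threshold (defaults: 2.2 and 3 of 4).  Anything short of that is reported
as unidentified / potentially novel.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .msp import MainSpectralProfile, SpectralLibrary
from .spectra import PeakList

__all__ = [
    "ScoredHit",
    "IdentificationCall",
    "score",
    "rank",
    "consensus_call",
    "DEFAULT_ID_THRESHOLD",
    "DEFAULT_MIN_REPLICATES",
]

DEFAULT_ID_THRESHOLD = 2.2
DEFAULT_MIN_REPLICATES = 3
DEFAULT_MZ_TOLERANCE = 2.0


@dataclass
class ScoredHit:
    entry_name: str
    log_score: float
    s_query: float
    s_ref: float
    s_int: float


@dataclass
class IdentificationCall:
    isolate_id: str
    replicate_results: list[tuple[str, list[ScoredHit]]]
    level: str  # "species" | "genus" | "unidentified"
    entry_name: str | None = None
    genus: str | None = None
    score: float = 0.0
    rubric: dict = field(default_factory=dict)

    @property
    def species_level(self) -> bool:
        return self.level == "species"


def _match_peaks(
    qmz: np.ndarray, rmz: np.ndarray, tolerance: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-m/z matching within tolerance."""
    candidates = []
    for qi, m in enumerate(qmz):
        lo = np.searchsorted(rmz, m - tolerance, side="left")
        hi = np.searchsorted(rmz, m + tolerance, side="right")
        for ri in range(lo, hi):
            candidates.append((abs(m - rmz[ri]), qi, ri))
    candidates.sort()
    used_q: set[int] = set()
    used_r: set[int] = set()
    pairs = []
    for _, qi, ri in candidates:
        if qi in used_q or ri in used_r:
            continue
        used_q.add(qi)
        used_r.add(ri)
        pairs.append((qi, ri))
    return pairs


def score(
    query: PeakList,
    ref: MainSpectralProfile,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    *,
    freq_weighted: bool = True,
) -> ScoredHit:
    """Score one peak list against one MSP on the 0-3 log-score scale.

    With ``freq_weighted`` (default) the reference-match fraction weights
    each reference peak by its MSP occurrence frequency, so missing a peak
    present in every replicate costs more than missing a borderline one.
    The score is invariant to a positive rescaling of query intensities
    (peak lists are max-normalized by construction).
    """
    if len(query) == 0:
        raise ValueError("query peak list has no peaks")
    pairs = _match_peaks(query.mz, ref.mz, mz_tolerance)
    n_match = len(pairs)
    s_query = n_match / len(query)
    if len(ref) == 0:
        s_ref = 0.0
    elif freq_weighted:
        w = ref.frequency
        matched_w = sum(w[ri] for _, ri in pairs)
        s_ref = float(matched_w / w.sum())
    else:
        s_ref = n_match / len(ref)

    if n_match < 3:
        # Too few pairs for a meaningful correlation: perfect mutual
        # coverage still counts as full agreement, otherwise neutral.
        full_cover = s_query == 1.0 and n_match == len(ref)
        s_int = 1.0 if full_cover else 0.5
    else:
        qv = np.array([query.intensity[qi] for qi, _ in pairs])
        rv = np.array([ref.intensity[ri] for _, ri in pairs])
        if qv.std() < 1e-12 and rv.std() < 1e-12:
            s_int = 1.0
        elif qv.std() < 1e-12 or rv.std() < 1e-12:
            s_int = 0.5
        else:
            s_int = max(0.0, float(np.corrcoef(qv, rv)[0, 1]))

    product = 1000.0 * s_query * s_ref * s_int
    log_score = max(0.0, math.log10(product)) if product > 0 else 0.0
    log_score = min(log_score, 3.0)
    return ScoredHit(ref.entry_name, log_score, s_query, s_ref, s_int)


def rank(
    query: PeakList,
    lib: SpectralLibrary,
    mz_tolerance: float = DEFAULT_MZ_TOLERANCE,
    *,
    freq_weighted: bool = True,
) -> list[ScoredHit]:
    """Score a query against every library entry, best first.

    Ties in log score are broken lexicographically by entry name so the
    ranking is deterministic.
    """
    if len(lib) == 0:
        raise ValueError("library is empty")
    hits = [score(query, e, mz_tolerance, freq_weighted=freq_weighted) for e in lib]
    hits.sort(key=lambda h: (-h.log_score, h.entry_name))
    return hits


def _genus_of(entry_name: str) -> str:
    from .concordance import parse_entry_name

    return parse_entry_name(entry_name).genus


def consensus_call(
    replicate_hits: Mapping[str, Sequence[ScoredHit]] | Sequence[Sequence[ScoredHit]],
    *,
    isolate_id: str = "",
    threshold: float = DEFAULT_ID_THRESHOLD,
    min_replicates: int = DEFAULT_MIN_REPLICATES,
    genus_threshold: float | None = None,
) -> IdentificationCall:
    """Apply the replicate-consensus rubric to per-replicate ranked hits.

    Species level requires at least ``min_replicates`` replicates whose top
    hit is the same entry with log score >= ``threshold``.  When
    ``genus_threshold`` is set, a genus-level fallback applies the same
    count at genus granularity; by default the fallback is disabled and
    anything short of species consensus is unidentified / potentially
    novel.  Raising ``threshold`` can only move calls toward unidentified.
    """
    if isinstance(replicate_hits, Mapping):
        items = [(str(k), list(v)) for k, v in replicate_hits.items()]
    else:
        items = [(str(i), list(v)) for i, v in enumerate(replicate_hits)]
    if not items:
        raise ValueError("at least one replicate is required")

    tops = [(rid, hits[0]) for rid, hits in items if hits]
    rubric = {
        "threshold": threshold,
        "min_replicates": min_replicates,
        "n_replicates": len(items),
        "genus_threshold": genus_threshold,
    }

    passing = [(rid, h) for rid, h in tops if h.log_score >= threshold]
    counts = Counter(h.entry_name for _, h in passing)
    if counts:
        best_entry, n_agree = min(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if n_agree >= min_replicates:
            scores = [h.log_score for _, h in passing if h.entry_name == best_entry]
            return IdentificationCall(
                isolate_id=isolate_id,
                replicate_results=items,
                level="species",
                entry_name=best_entry,
                genus=_genus_of(best_entry),
                score=float(np.median(scores)),
                rubric=rubric,
            )

    if genus_threshold is not None:
        passing_g = [(rid, h) for rid, h in tops if h.log_score >= genus_threshold]
        gcounts = Counter(_genus_of(h.entry_name) for _, h in passing_g)
        if gcounts:
            best_genus, n_agree = min(gcounts.items(), key=lambda kv: (-kv[1], kv[0]))
            if n_agree >= min_replicates:
                scores = [h.log_score for _, h in passing_g
                          if _genus_of(h.entry_name) == best_genus]
                return IdentificationCall(
                    isolate_id=isolate_id,
                    replicate_results=items,
                    level="genus",
                    genus=best_genus,
                    score=float(np.median(scores)),
                    rubric=rubric,
                )

    best = max((h.log_score for _, h in tops), default=0.0)
    top_entry = None
    if tops:
        top_entry = min(tops, key=lambda t: (-t[1].log_score, t[1].entry_name))[1].entry_name
    return IdentificationCall(
        isolate_id=isolate_id,
        replicate_results=items,
        level="unidentified",
        entry_name=top_entry,
        genus=_genus_of(top_entry) if top_entry else None,
        score=float(best),
        rubric=rubric,
    )
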