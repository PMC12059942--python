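"""Score allosteric-site predictions against known sites.

The unit of evaluation is the *topmost* prediction of each tool for each
protein, scored with the Jaccard index

    JI = |K ∩ P| / |K ∪ P|

where K and P are the known and predicted residue sets.  JI is 1 when the
sets are identical, 0 when they share no residue, and is pulled down when
the prediction includes many residues outside the known site.  For
multimeric proteins with several known copies of the site, the topmost
prediction is compared to every known site and the best JI is kept.  Tool
failures (no prediction) score 0 and stay in the summaries, so medians and
means reflect reliability as well as accuracy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from statistics import mean, median

import numpy as np
import pandas as pd

from .core_model import (
    BenchmarkResult,
    PredictionRecord,
    ResidueRef,
    StructureModel,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AccuracyCurve",
    "jaccard_index",
    "best_ji_match",
    "normalize_prediction",
    "centroid_distance",
    "score_prediction",
    "accuracy_curve",
    "summarize",
    "results_to_frame",
]

DEFAULT_CUTOFFS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)


def jaccard_index(K: frozenset[ResidueRef] | set, P: frozenset[ResidueRef] | set) -> float:
    """|K∩P| / |K∪P| for known (K) and predicted (P) residue sets.

    K must be non-empty; an empty P scores 0 (tool failure convention).
    """
    if not K:
        raise ValueError("empty_known_site: the known site may not be empty")
    if not P:
        return 0.0
    K, P = set(K), set(P)
    return len(K & P) / len(K | P)


def best_ji_match(
    topmost: frozenset[ResidueRef] | set,
    known_sites: list[frozenset[ResidueRef]],
) -> tuple[float, int]:
    """Best JI of the topmost prediction over all known sites.

    Multimers carry one known site per bound modulator copy; the prediction
    is credited with the best-matching one.  Ties go to the lowest index.
    """
    if not known_sites:
        raise ValueError("at least one known site is required")
    best = (0.0, 0)
    for i, site in enumerate(known_sites):
        ji = jaccard_index(site, topmost)
        if ji > best[0]:
            best = (ji, i)
    return best


def normalize_prediction(
    p: PredictionRecord, s: StructureModel
) -> tuple[PredictionRecord, int]:
    """Remove spurious residues — identifiers absent from the structure.

    Some tools emit residue numbers that do not exist in the input file;
    those are dropped while the valid residues are retained.  Sites emptied
    entirely are removed.  Returns the cleaned record and the number of
    spurious residues removed.
    """
    valid: set[ResidueRef] = set()
    for chain in s.chains.values():
        valid.update(chain.residues)
    cleaned: list[tuple[frozenset[ResidueRef], float | None]] = []
    n_spurious = 0
    for residues, score in p.ranked_sites:
        kept = frozenset(r for r in residues if r in valid)
        n_spurious += len(residues) - len(kept)
        if kept:
            cleaned.append((kept, score))
    if n_spurious:
        logger.info("%s/%s: removed %d spurious residue(s)",
                    p.tool, p.protein_id, n_spurious)
    return PredictionRecord(tool=p.tool, protein_id=p.protein_id,
                            ranked_sites=cleaned), n_spurious


def _ca_centroid(site: frozenset[ResidueRef], s: StructureModel) -> np.ndarray:
    coords = [(a.x, a.y, a.z) for a in s.atoms
              if a.name == "CA" and not a.is_hetero and a.residue in site]
    if not coords:
        raise ValueError(f"site {sorted(site)[:3]}... has no resolvable CA atom")
    return np.asarray(coords).mean(axis=0)


def centroid_distance(
    site_a: frozenset[ResidueRef],
    site_b: frozenset[ResidueRef],
    s: StructureModel,
) -> float:
    """Distance (Å) between the unweighted Cα centroids of two sites.

    The inverse of this distance estimates the 3D proximity of the
    predicted and known sites independently of residue-set overlap.
    """
    return float(np.linalg.norm(_ca_centroid(site_a, s) - _ca_centroid(site_b, s)))


def score_prediction(
    p: PredictionRecord,
    known_sites: list[frozenset[ResidueRef]],
    s: StructureModel | None = None,
    best_of_k: bool = False,
) -> BenchmarkResult:
    """Score one prediction record against the known sites of its protein.

    By default only the topmost-ranked site is scored; ``best_of_k`` scores
    every ranked site and keeps the best (for tools that do not rank their
    output).  An empty record scores JI 0.
    """
    if not p.ranked_sites:
        return BenchmarkResult(protein_id=p.protein_id, tool=p.tool,
                               ji=0.0, matched_known_site_index=0, failed=True)
    candidates = p.ranked_sites if best_of_k else p.ranked_sites[:1]
    best_ji, best_idx, best_site = 0.0, 0, candidates[0][0]
    for residues, _score in candidates:
        ji, idx = best_ji_match(residues, known_sites)
        if ji > best_ji:
            best_ji, best_idx, best_site = ji, idx, residues
    dist = None
    if s is not None and best_site:
        try:
            dist = centroid_distance(best_site, known_sites[best_idx], s)
        except ValueError:
            logger.warning("%s/%s: no CA atoms for centroid distance",
                           p.tool, p.protein_id)
    return BenchmarkResult(protein_id=p.protein_id, tool=p.tool, ji=best_ji,
                           matched_known_site_index=best_idx,
                           centroid_distance=dist)


@dataclass
class AccuracyCurve:
    """Percentage of proteins whose topmost JI exceeds each cutoff."""

    cutoffs: tuple[float, ...]
    percent_above: dict[str, list[float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tool, values in self.percent_above.items():
            if any(b > a + 1e-9 for a, b in zip(values, values[1:])):
                raise ValueError(f"accuracy curve for {tool} is not non-increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.percent_above, index=list(self.cutoffs)) \
                 .rename_axis("cutoff")


def _group_by_tool(results: list[BenchmarkResult]) -> dict[str, list[BenchmarkResult]]:
    seen: set[tuple[str, str]] = set()
    by_tool: dict[str, list[BenchmarkResult]] = {}
    for r in results:
        key = (r.protein_id, r.tool)
        if key in seen:
            raise ValueError(f"duplicate result for {key}")
        seen.add(key)
        by_tool.setdefault(r.tool, []).append(r)
    return by_tool


def accuracy_curve(
    results: list[BenchmarkResult],
    cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
) -> AccuracyCurve:
    """Per tool and cutoff c: 100 × |{proteins with JI > c}| / |proteins|."""
    by_tool = _group_by_tool(results)
    percent = {
        tool: [100.0 * sum(r.ji > c for r in rs) / len(rs) for c in cutoffs]
        for tool, rs in sorted(by_tool.items())
    }
    return AccuracyCurve(cutoffs=tuple(cutoffs), percent_above=percent)


def summarize(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Per-tool median and mean JI over all proteins (failures count as 0).

    The JI distributions are highly skewed toward 0, so the median is the
    primary measure of central tendency; the mean is reported alongside.
    """
    by_tool = _group_by_tool(results)
    rows = []
    for tool, rs in sorted(by_tool.items()):
        jis = [r.ji for r in rs]
        rows.append({
            "tool": tool,
            "median_ji": float(median(jis)),
            "mean_ji": float(mean(jis)),
            "n": len(jis),
            "n_failed": sum(r.failed for r in rs),
        })
    return pd.DataFrame(rows).set_index("tool")


def results_to_frame(results: list[BenchmarkResult]) -> pd.DataFrame:
    """Long-format results table (one row per protein × tool)."""
    return pd.DataFrame([
        {
            "protein_id": r.protein_id,
            "tool": r.tool,
            "ji": r.ji,
            "matched_site": r.matched_known_site_index,
            "centroid_distance_A": r.centroid_distance,
            "inverse_distance": r.inverse_distance,
        }
        for r in results
    ])
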