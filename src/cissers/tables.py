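"""The three result tables: Summary, Best (greedy combination), Top.

Summary reports, per enzyme (or isoschizomer group), how many input
sequences contain at least one in-region recognition site, the total count
of sites, and the percentage of sequences cut.  Best repeatedly picks the
enzyme covering the most not-yet-cut sequences (greedy set cover — the
right shape for choosing a minimal enzyme panel that digests nearly every
transcript in a target window).  Top filters Summary at a percentage
threshold, defaulting to 95%.

Percentages are computed with exact integer arithmetic and rounded
half-up to two decimals only at presentation time.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Optional

import pandas as pd

from .scanner import SiteIndex

__all__ = ["pct", "summarize", "greedy_best", "top_table"]

SUMMARY_COLUMNS = ["pattern_name", "site", "n_seqs_cut", "n_total_cuts", "pct_seqs_cut"]
BEST_COLUMNS = ["rank", "pattern_name", "newly_covered", "cumulative_pct", "precut_cuts"]


def pct(numerator: int, denominator: int) -> float:
    """Percentage rounded half-up to 2 decimals (presentation only)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    q = Decimal(numerator) * 100 / Decimal(denominator)
    return float(q.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def summarize(
    site_index: SiteIndex,
    n_records: Optional[int] = None,
    groups: Optional[dict[str, tuple[str, bool]]] = None,
    sites: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Build the Summary table from a census.

    ``groups`` (as produced by ``EnzymeDatabase.group_representatives``)
    collapses isoschizomers: one row per group, labeled with the
    alphabetically first member plus a ``*`` flag when the group has more
    than one member.  Rows are ordered by descending percentage, then name.
    """
    n = site_index.n_records if n_records is None else n_records
    if n <= 0:
        raise ValueError("summarize requires a positive record count")
    rows = []
    emitted: set[str] = set()
    for name in sorted(site_index.pattern_names):
        label, multi = (name, False) if groups is None else groups.get(name, (name, False))
        if label in emitted:
            continue  # isoschizomer of an already-emitted group
        emitted.add(label)
        shown = label + ("*" if multi else "")
        rows.append(
            {
                "pattern_name": shown,
                "site": "" if sites is None else sites.get(name, ""),
                "n_seqs_cut": site_index.n_records_matched(name),
                "n_total_cuts": site_index.n_total_matches(name),
                "pct_seqs_cut": pct(site_index.n_records_matched(name), n),
            }
        )
    table = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    table = table.sort_values(
        ["pct_seqs_cut", "pattern_name"], ascending=[False, True]
    ).reset_index(drop=True)
    return table


def greedy_best(
    site_index: SiteIndex,
    n_records: Optional[int] = None,
    target_pct: Optional[float] = None,
    max_enzymes: Optional[int] = None,
) -> pd.DataFrame:
    """Greedy enzyme-combination table.

    Each step selects the pattern cutting the most not-yet-covered records;
    those records are removed and the next best pattern is found.  Ties are
    broken by larger total cut count, then alphabetical name.  Iteration
    stops when no pattern adds coverage, when cumulative coverage reaches
    ``target_pct``, or after ``max_enzymes`` rows.  Pre-cut-area counts are
    carried per selected pattern as metadata, not as coverage.
    """
    n = site_index.n_records if n_records is None else n_records
    if n <= 0:
        raise ValueError("greedy_best requires a positive record count")
    remaining: dict[str, set[str]] = {
        name: set(site_index.records_cut(name)) for name in site_index.pattern_names
    }
    covered: set[str] = set()
    rows = []
    rank = 0
    while True:
        if max_enzymes is not None and rank >= max_enzymes:
            break
        candidates = sorted(
            (
                (-len(remaining[name] - covered), -site_index.n_total_matches(name), name)
                for name in remaining
            )
        )
        if not candidates or candidates[0][0] == 0:
            break
        neg_gain, _neg_total, best_name = candidates[0]
        best_gain = -neg_gain
        covered |= remaining[best_name]
        rank += 1
        rows.append(
            {
                "rank": rank,
                "pattern_name": best_name,
                "newly_covered": best_gain,
                "cumulative_pct": pct(len(covered), n),
                "precut_cuts": site_index.n_precut_matches(best_name),
            }
        )
        if target_pct is not None and rows[-1]["cumulative_pct"] >= target_pct:
            break
    return pd.DataFrame(rows, columns=BEST_COLUMNS)


def top_table(summary: pd.DataFrame, threshold_pct: float = 95.0) -> pd.DataFrame:
    """Filter the Summary table to enzymes cutting at least
    ``threshold_pct`` percent of sequences (default 95, adjustable)."""
    if not 0 <= threshold_pct <= 100:
        raise ValueError("threshold_pct must be within [0, 100]")
    return summary[summary["pct_seqs_cut"] >= threshold_pct].reset_index(drop=True)
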