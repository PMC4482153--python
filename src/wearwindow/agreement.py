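"""Method-agreement analysis for wear windows.

Two methods (algorithm, visual inspection, participant log) each propose a
window of consecutive wear days for the same signal.  Agreement between them
is summarized categorically rather than with chance-corrected statistics
(kappa/ICC assume a fixed rating scale, which a variable-length signal does
not offer):

* ``exact`` — same dates, same number of days.
* ``same_length_shift_1`` / ``same_length_shift_ge2`` — same number of days,
  start (hence end) dates shifted by 1 / by 2 or more days.
* ``diff_length_1`` / ``diff_length_ge2`` — window lengths differ by 1 / by
  2 or more days.
* ``one_empty`` / ``both_empty`` — degenerate cases where a method found no
  wear at all.

The headline summary statistic is the *combined same-length agreement*: the
share of pairs whose windows contain the same total number of days once
shifts in calendar dates are allowed (exact + both shift categories).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .wear_window import WearWindow

__all__ = [
    "CATEGORIES",
    "SAME_LENGTH_CATEGORIES",
    "AgreementResult",
    "AgreementSummary",
    "compare_windows",
    "agreement_summary",
    "format_summary_table",
]

CATEGORIES = (
    "exact",
    "same_length_shift_1",
    "same_length_shift_ge2",
    "diff_length_1",
    "diff_length_ge2",
    "one_empty",
    "both_empty",
)
SAME_LENGTH_CATEGORIES = ("exact", "same_length_shift_1", "same_length_shift_ge2")


@dataclass(frozen=True)
class AgreementResult:
    """Categorical comparison of two wear windows.

    ``shift_days`` is |Δ start date| and is only meaningful (non-zero) for
    equal-length non-empty windows, where it equals |Δ end date| as well.
    ``wear_hours_diff`` is ``a − b`` when both windows carry wear hours.
    ``method_with_more_days`` names the method whose window is longer, for
    the different-length categories.
    """

    category: str
    shift_days: int = 0
    length_diff: int = 0
    wear_hours_diff: float | None = None
    method_with_more_days: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown agreement category {self.category!r}")
        if self.shift_days < 0 or self.length_diff < 0:
            raise ValueError("shift_days and length_diff are magnitudes (>= 0)")


def compare_windows(
    a: WearWindow,
    b: WearWindow,
    label_a: str | None = None,
    label_b: str | None = None,
) -> AgreementResult:
    """Classify the (dis)agreement between two windows for the same signal.

    Labels default to each window's ``method`` field.  The comparison is
    symmetric up to the sign of ``wear_hours_diff`` and the swap of
    ``method_with_more_days``.
    """
    label_a = label_a if label_a is not None else a.method
    label_b = label_b if label_b is not None else b.method

    hours = None
    if a.total_wear_hours is not None and b.total_wear_hours is not None:
        hours = a.total_wear_hours - b.total_wear_hours

    if a.n_days == 0 and b.n_days == 0:
        return AgreementResult("both_empty", wear_hours_diff=hours)
    if a.n_days == 0 or b.n_days == 0:
        longer = label_a if a.n_days > b.n_days else label_b
        return AgreementResult(
            "one_empty",
            length_diff=abs(a.n_days - b.n_days),
            wear_hours_diff=hours,
            method_with_more_days=longer,
        )

    length_diff = abs(a.n_days - b.n_days)
    if length_diff == 0:
        shift = abs((a.start_date - b.start_date).days)
        if shift == 0:
            return AgreementResult("exact", wear_hours_diff=hours)
        cat = "same_length_shift_1" if shift == 1 else "same_length_shift_ge2"
        return AgreementResult(cat, shift_days=shift, wear_hours_diff=hours)

    longer = label_a if a.n_days > b.n_days else label_b
    cat = "diff_length_1" if length_diff == 1 else "diff_length_ge2"
    return AgreementResult(
        cat, length_diff=length_diff, wear_hours_diff=hours,
        method_with_more_days=longer,
    )


@dataclass(frozen=True)
class AgreementSummary:
    """Counts and percentages of agreement categories over paired windows."""

    n_pairs: int
    counts: dict
    percentages: dict
    combined_same_length_count: int
    combined_same_length_pct: float
    mean_wear_hours_diff: dict
    more_days_counts: dict

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "counts": dict(self.counts),
            "percentages": dict(self.percentages),
            "combined_same_length_count": self.combined_same_length_count,
            "combined_same_length_pct": self.combined_same_length_pct,
            "mean_wear_hours_diff": dict(self.mean_wear_hours_diff),
            "more_days_counts": dict(self.more_days_counts),
        }


def agreement_summary(pairs: list[AgreementResult]) -> AgreementSummary:
    """Aggregate pairwise results into a category table.

    Per-category percentages partition 100% over the pairs; the combined
    same-length percentage pools ``exact`` with both shift categories ("one
    or more shifts in calendar dates allowed, same total number of days").
    Mean wear-hour differences are reported per shift category (the
    magnitude of disagreement within same-length pairs), and
    ``more_days_counts`` tallies which method had the longer window among
    different-length pairs.
    """
    if not pairs:
        raise ValueError("agreement_summary needs at least one pair")
    n = len(pairs)
    counts = Counter(r.category for r in pairs)
    counts = {c: counts.get(c, 0) for c in CATEGORIES}
    percentages = {c: 100.0 * counts[c] / n for c in CATEGORIES}
    same_len = sum(counts[c] for c in SAME_LENGTH_CATEGORIES)

    mean_diff: dict[str, float | None] = {}
    for cat in ("same_length_shift_1", "same_length_shift_ge2"):
        diffs = [
            r.wear_hours_diff
            for r in pairs
            if r.category == cat and r.wear_hours_diff is not None
        ]
        mean_diff[cat] = sum(diffs) / len(diffs) if diffs else None

    more_days = Counter(
        r.method_with_more_days
        for r in pairs
        if r.method_with_more_days is not None
    )
    return AgreementSummary(
        n_pairs=n,
        counts=counts,
        percentages=percentages,
        combined_same_length_count=same_len,
        combined_same_length_pct=100.0 * same_len / n,
        mean_wear_hours_diff=mean_diff,
        more_days_counts=dict(more_days),
    )


_LABELS = {
    "exact": "Complete agreement",
    "same_length_shift_1": "Wear window shifted by 1 day in one method",
    "same_length_shift_ge2": "Wear window shifted by >=2 days in one method",
    "diff_length_1": "Differed by 1 day",
    "diff_length_ge2": "Differed by >=2 days",
    "one_empty": "One method found no wear",
    "both_empty": "Neither method found wear",
}


def format_summary_table(summary: AgreementSummary) -> str:
    """Plain-text category table (same-length block, then different-length)."""
    c, p = summary.counts, summary.percentages
    lines = [f"Paired comparisons: n = {summary.n_pairs}", ""]
    lines.append("Same number of days in wear window")
    for cat in SAME_LENGTH_CATEGORIES:
        lines.append(f"  {_LABELS[cat]:<46} {c[cat]:>4} ({p[cat]:.1f}%)")
        md = summary.mean_wear_hours_diff.get(cat)
        if md is not None:
            lines.append(f"    Average difference in hours of wear: {md:+.1f}")
    lines.append(
        f"  {'Total':<46} {summary.combined_same_length_count:>4} "
        f"({summary.combined_same_length_pct:.1f}%)"
    )
    lines.append("Different number of days in wear window")
    diff_total = sum(c[cat] for cat in ("diff_length_1", "diff_length_ge2"))
    for cat in ("diff_length_1", "diff_length_ge2"):
        lines.append(f"  {_LABELS[cat]:<46} {c[cat]:>4} ({p[cat]:.1f}%)")
    lines.append(
        f"  {'Total':<46} {diff_total:>4} ({100.0 * diff_total / summary.n_pairs:.1f}%)"
    )
    for cat in ("one_empty", "both_empty"):
        if c[cat]:
            lines.append(f"{_LABELS[cat]:<48} {c[cat]:>4} ({p[cat]:.1f}%)")
    if summary.more_days_counts:
        parts = ", ".join(
            f"{k}: {v}" for k, v in sorted(summary.more_days_counts.items())
        )
        lines.append(f"Method with more days of wear — {parts}")
    return "\n".join(lines)
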