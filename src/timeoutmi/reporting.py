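"""Run-level summary reports, figures, and printed-style percentages."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np

from . import __version__


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """Percentage share rounded half-up, e.g. percent(683, 6592) == 10.36."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round_half_up(100.0 * numerator / denominator, ndigits)


@dataclass
class RatioRow:
    """One analysis line: a ratio of means with its confidence interval."""

    label: str
    ratio: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    p_value: Optional[float] = None
    note: str = ""


@dataclass
class RunReport:
    n_enrolled: int
    n_accessed: int
    n_visits: int
    n_views: int
    n_timed_out: int
    n_participants_with_timeout: int
    median_observed_min: Optional[float]
    iqr_low_min: Optional[float]
    iqr_high_min: Optional[float]
    analyses: list[RatioRow] = field(default_factory=list)
    seed: Optional[int] = None
    config_hash: Optional[str] = None

    @property
    def pct_accessed(self) -> float:
        return percent(self.n_accessed, self.n_enrolled)

    @property
    def pct_timed_out(self) -> float:
        return percent(self.n_timed_out, self.n_views) if self.n_views else 0.0

    @property
    def pct_participants_with_timeout(self) -> float:
        if self.n_accessed == 0:
            return 0.0
        return percent(self.n_participants_with_timeout, self.n_accessed)

    def to_text(self) -> str:
        lines = [
            "Engagement run report",
            "=====================",
            f"Enrolled participants:           {self.n_enrolled}",
            f"Accessed at least once:          {self.n_accessed}"
            f" ({self.pct_accessed:.2f}%, {self.n_accessed}/{self.n_enrolled})",
            f"Intervention visits:             {self.n_visits}",
            f"Unique page views:               {self.n_views}",
            f"Timed-out page views:            {self.n_timed_out}"
            + (
                f" ({self.pct_timed_out:.2f}%, {self.n_timed_out}/{self.n_views})"
                if self.n_views
                else ""
            ),
            f"Participants with >=1 time-out:  {self.n_participants_with_timeout}"
            + (
                f" ({self.pct_participants_with_timeout:.2f}%,"
                f" {self.n_participants_with_timeout}/{self.n_accessed})"
                if self.n_accessed
                else ""
            ),
        ]
        if self.median_observed_min is None:
            lines.append("Observed page-view median:       unavailable (all views timed out)")
        else:
            lines.append(
                f"Observed page-view median (min): {self.median_observed_min:.2f}"
                f" (IQR {self.iqr_low_min:.2f}-{self.iqr_high_min:.2f})"
            )
        if self.analyses:
            lines.append("")
            lines.append("Ratio-of-means analyses (motivational vs prescriptive):")
            for row in self.analyses:
                if row.ratio is None:
                    lines.append(f"  {row.label}: unavailable ({row.note})")
                else:
                    txt = (
                        f"  {row.label}: {row.ratio:.2f}"
                        f" (95% CI {row.ci_low:.2f}-{row.ci_high:.2f})"
                    )
                    if row.p_value is not None:
                        txt += f"; P={row.p_value:.2f}"
                    if row.note:
                        txt += f"  [{row.note}]"
                    lines.append(txt)
        lines.append("")
        lines.append("Provenance:")
        lines.append(f"  package version: {__version__}")
        if self.seed is not None:
            lines.append(f"  seed: {self.seed}")
        if self.config_hash is not None:
            lines.append(f"  config hash: {self.config_hash}")
        return "\n".join(lines) + "\n"

    def to_keyvalue(self) -> str:
        pairs = [
            ("n_enrolled", self.n_enrolled),
            ("n_accessed", self.n_accessed),
            ("pct_accessed", f"{self.pct_accessed:.2f}"),
            ("n_visits", self.n_visits),
            ("n_views", self.n_views),
            ("n_timed_out", self.n_timed_out),
            ("pct_timed_out", f"{self.pct_timed_out:.2f}"),
            ("n_participants_with_timeout", self.n_participants_with_timeout),
            (
                "pct_participants_with_timeout",
                f"{self.pct_participants_with_timeout:.2f}",
            ),
            ("median_observed_min", self.median_observed_min),
            ("iqr_low_min", self.iqr_low_min),
            ("iqr_high_min", self.iqr_high_min),
            ("version", __version__),
            ("seed", self.seed),
            ("config_hash", self.config_hash),
        ]
        for row in self.analyses:
            key = row.label.lower().replace(" ", "_").replace("-", "_")
            pairs.append((f"ratio[{key}]", row.ratio))
            pairs.append((f"ci_low[{key}]", row.ci_low))
            pairs.append((f"ci_high[{key}]", row.ci_high))
        return "\n".join(f"{k}={v}" for k, v in pairs) + "\n"

    def check_percentages(self) -> None:
        """Verify every printed percentage against its count pair."""
        assert self.pct_accessed == percent(self.n_accessed, self.n_enrolled)
        if self.n_views:
            assert self.pct_timed_out == percent(self.n_timed_out, self.n_views)
        if self.n_accessed:
            assert self.pct_participants_with_timeout == percent(
                self.n_participants_with_timeout, self.n_accessed
            )


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def build_report(
    records,
    participants,
    n_visits: int,
    analyses: Optional[Sequence[RatioRow]] = None,
    seed: Optional[int] = None,
    config_text: Optional[str] = None,
) -> RunReport:
    """Assemble a RunReport from parsed records and the participant table."""
    from .weblog import summarize_views

    n_enrolled = len(participants)
    if records:
        summary = summarize_views(records)
        report = RunReport(
            n_enrolled=n_enrolled,
            n_accessed=summary["n_participants"],
            n_visits=n_visits,
            n_views=summary["n_views"],
            n_timed_out=summary["n_timed_out"],
            n_participants_with_timeout=summary["n_participants_with_timeout"],
            median_observed_min=summary["median_observed_min"],
            iqr_low_min=summary["iqr_low_min"],
            iqr_high_min=summary["iqr_high_min"],
        )
    else:
        report = RunReport(
            n_enrolled=n_enrolled,
            n_accessed=0,
            n_visits=0,
            n_views=0,
            n_timed_out=0,
            n_participants_with_timeout=0,
            median_observed_min=None,
            iqr_low_min=None,
            iqr_high_min=None,
        )
    report.analyses = list(analyses or [])
    report.seed = seed
    if config_text is not None:
        report.config_hash = config_hash(config_text)
    report.check_percentages()
    return report


def plot_duration_histogram(records, path, bins: int = 40) -> None:
    """Histogram of observed viewing minutes, excluding timed-out views."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    observed = np.array(
        [r.duration_min for r in records if not r.timed_out], dtype=float
    )
    fig, ax = plt.subplots(figsize=(7, 4.5))
    ax.hist(observed, bins=bins, color="#4477aa", edgecolor="white")
    ax.set_xlabel("Minutes spent viewing an intervention page")
    ax.set_ylabel("Page views")
    ax.set_title("Observed page-view durations (timed-out views excluded)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
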