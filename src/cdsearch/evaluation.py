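"""TREC-style evaluation: qrels/run I/O, rank metrics, paired tests.

Grades are 0 (not relevant), 1 (possibly relevant), 2 (definitely
relevant); possibly and definitely are conflated to a single relevant
set for all metrics.  Unjudged pairs default to not relevant — the
standard pooled-assessment convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

from scipy import stats

GRADES = (0, 1, 2)
MAX_RUN_DEPTH = 500


@dataclass
class Judgments:
    """Graded relevance judgments keyed by (query_id, passage_id)."""

    grades: dict[tuple[str, str], int] = field(default_factory=dict)

    def add(self, query_id: str, passage_id: str, grade: int) -> None:
        if grade not in GRADES:
            raise ValueError(f"grade must be one of {GRADES}, got {grade!r}")
        self.grades[(query_id, passage_id)] = grade

    def grade(self, query_id: str, passage_id: str) -> int:
        return self.grades.get((query_id, passage_id), 0)

    def is_relevant(self, query_id: str, passage_id: str) -> bool:
        return self.grade(query_id, passage_id) >= 1

    def relevant(self, query_id: str) -> set[str]:
        return {
            pid for (qid, pid), g in self.grades.items() if qid == query_id and g >= 1
        }

    def query_ids(self) -> list[str]:
        return sorted({qid for qid, _ in self.grades})


@dataclass
class RunRecord:
    """One query's ranked system output (ranks contiguous from 1)."""

    query_id: str
    entries: list[tuple[str, float]] = field(default_factory=list)
    tag: str = "run"

    def __post_init__(self) -> None:
        if len(self.entries) > MAX_RUN_DEPTH:
            raise ValueError(
                f"run for {self.query_id!r} exceeds {MAX_RUN_DEPTH} entries"
            )

    def passage_ids(self) -> list[str]:
        return [pid for pid, _ in self.entries]


# -- TREC file formats ---------------------------------------------------


def read_qrels(path: Union[str, Path]) -> Judgments:
    """Read TREC qrels lines ``qid 0 pid grade``."""
    judgments = Judgments()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            qid, _, pid, grade = parts
            judgments.add(qid, pid, int(grade))
    return judgments


def write_qrels(judgments: Judgments, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (qid, pid), grade in sorted(judgments.grades.items()):
            fh.write(f"{qid} 0 {pid} {grade}\n")


def read_run(path: Union[str, Path]) -> dict[str, RunRecord]:
    """Read TREC run lines ``qid Q0 pid rank score tag``."""
    per_query: dict[str, list[tuple[int, str, float, str]]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            qid, _, pid, rank, score, tag = parts
            per_query.setdefault(qid, []).append((int(rank), pid, float(score), tag))
    runs = {}
    for qid, rows in per_query.items():
        rows.sort()
        runs[qid] = RunRecord(
            query_id=qid,
            entries=[(pid, score) for _, pid, score, _ in rows],
            tag=rows[0][3],
        )
    return runs


def write_run(runs: Mapping[str, RunRecord], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for qid in sorted(runs):
            run = runs[qid]
            for rank, (pid, score) in enumerate(run.entries, 1):
                fh.write(f"{qid} Q0 {pid} {rank} {score:.6f} {run.tag}\n")


# -- metrics -------------------------------------------------------------


def precision_at_n(run: RunRecord, judgments: Judgments, n: int) -> float:
    """|relevant in top n| / n; short runs pad with non-relevant."""
    if n < 1:
        raise ValueError("n must be >= 1")
    hits = sum(
        1 for pid in run.passage_ids()[:n] if judgments.is_relevant(run.query_id, pid)
    )
    return hits / n


def r_precision(run: RunRecord, judgments: Judgments) -> Optional[float]:
    """r / R with r counted in the top R; None (with a warning) if R = 0."""
    total = len(judgments.relevant(run.query_id))
    if total == 0:
        warnings.warn(
            f"query {run.query_id!r} has no relevant passages; R-precision undefined",
            stacklevel=2,
        )
        return None
    hits = sum(
        1
        for pid in run.passage_ids()[:total]
        if judgments.is_relevant(run.query_id, pid)
    )
    return hits / total


def _dcg(gains: Sequence[int]) -> float:
    """Binary-gain DCG: G(1) undiscounted, G(p)/log2(p) for p >= 2."""
    total = 0.0
    for p, gain in enumerate(gains, 1):
        if gain:
            total += gain if p == 1 else gain / math.log2(p)
    return total


def ndcg_at_n(run: RunRecord, judgments: Judgments, n: int) -> float:
    """Binary-gain nDCG at n; 0 when the query has no relevant passages."""
    if n < 1:
        raise ValueError("n must be >= 1")
    total_relevant = len(judgments.relevant(run.query_id))
    if total_relevant == 0:
        return 0.0
    gains = [
        1 if judgments.is_relevant(run.query_id, pid) else 0
        for pid in run.passage_ids()[:n]
    ]
    ideal = [1] * min(total_relevant, n)
    idcg = _dcg(ideal)
    return _dcg(gains) / idcg if idcg > 0 else 0.0


def reciprocal_rank(run: RunRecord, judgments: Judgments) -> float:
    """1 / rank of the first relevant passage; 0 if none retrieved."""
    for rank, pid in enumerate(run.passage_ids(), 1):
        if judgments.is_relevant(run.query_id, pid):
            return 1.0 / rank
    return 0.0


def mrr(runs: Iterable[RunRecord], judgments: Judgments) -> float:
    """Mean reciprocal rank over queries (no-relevant queries contribute 0)."""
    values = [reciprocal_rank(run, judgments) for run in runs]
    if not values:
        raise ValueError("mrr requires at least one query")
    return sum(values) / len(values)


# -- metric registry and run-level evaluation ----------------------------

MetricFn = Callable[[RunRecord, Judgments], Optional[float]]


def _metric_fn(name: str) -> MetricFn:
    name = name.lower()
    if name == "mrr" or name == "rr":
        return reciprocal_rank
    if name == "rprec":
        return r_precision
    if name.startswith("p") and name[1:].isdigit():
        n = int(name[1:])
        return lambda run, judgments: precision_at_n(run, judgments, n)
    if name.startswith("ndcg") and name[4:].isdigit():
        n = int(name[4:])
        return lambda run, judgments: ndcg_at_n(run, judgments, n)
    raise ValueError(f"unknown metric {name!r}")


def per_query_metric(
    runs: Mapping[str, RunRecord],
    judgments: Judgments,
    metric: Union[str, MetricFn],
) -> dict[str, float]:
    """Metric value per query; queries where the metric is undefined are skipped."""
    fn = _metric_fn(metric) if isinstance(metric, str) else metric
    out = {}
    for qid in sorted(runs):
        value = fn(runs[qid], judgments)
        if value is not None:
            out[qid] = value
    return out


def evaluate_runs(
    runs: Mapping[str, RunRecord],
    judgments: Judgments,
    metrics: Sequence[str] = ("p5", "rprec", "ndcg10", "mrr"),
) -> dict[str, dict[str, float]]:
    """Per-query table plus a ``mean`` row for each requested metric."""
    table: dict[str, dict[str, float]] = {}
    for name in metrics:
        per_query = per_query_metric(runs, judgments, name)
        table[name] = dict(per_query)
        table[name]["mean"] = (
            sum(per_query.values()) / len(per_query) if per_query else 0.0
        )
    return table


def paired_comparison(
    runs_a: Mapping[str, RunRecord],
    runs_b: Mapping[str, RunRecord],
    judgments: Judgments,
    metric: Union[str, MetricFn],
) -> tuple[float, float]:
    """Paired t-test of per-query metric differences (a minus b).

    Returns (mean difference, p-value).  Degenerate zero-variance
    differences give p = 1.0 when the mean difference is 0 and p = 0.0
    otherwise.
    """
    shared = sorted(set(runs_a) & set(runs_b))
    if len(shared) < 2:
        raise ValueError("paired comparison requires at least 2 shared queries")
    values_a = per_query_metric({q: runs_a[q] for q in shared}, judgments, metric)
    values_b = per_query_metric({q: runs_b[q] for q in shared}, judgments, metric)
    qids = sorted(set(values_a) & set(values_b))
    if len(qids) < 2:
        raise ValueError("paired comparison requires at least 2 defined queries")
    diffs = [values_a[q] - values_b[q] for q in qids]
    mean_delta = sum(diffs) / len(diffs)
    if all(d == diffs[0] for d in diffs):
        return mean_delta, 1.0 if mean_delta == 0.0 else 0.0
    result = stats.ttest_rel([values_a[q] for q in qids], [values_b[q] for q in qids])
    return mean_delta, float(result.pvalue)
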