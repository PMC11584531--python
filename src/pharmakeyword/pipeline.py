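"""End-to-end study orchestration.

A study mirrors the two-phase design the pipeline replicates: assemble
per-drug corpora and a partitioned control pool, then run a planned
list of corpus-pair comparisons — validation pairs (known drugs vs each
other and vs control groups) and application pairs (new drugs vs
control groups and vs each other). Drug-vs-drug comparisons remove
posts shared by both corpora; drug-vs-control comparisons use the
control group as drawn (controls contain no drug mentions by
construction). Keyword adjudication is never automatic: an optional
highlight dictionary only annotates retained words.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diffstats import ComparisonResult, TestConfig, compare_corpora
from .ingest import Post, filter_by_date
from .lexicon import (
    CorpusAssignment,
    DrugLexicon,
    build_corpora,
    partition_controls,
    remove_shared,
)
from .textproc import TokenizedText, build_corpus, tokenize

log = logging.getLogger(__name__)

__all__ = [
    "StudyPlan",
    "StudyReport",
    "HighlightReport",
    "default_study_plan",
    "run_study",
    "corpus_summary",
    "highlight_report",
]


@dataclass(frozen=True)
class StudyPlan:
    """Ordered comparisons plus everything needed to reproduce them.

    A comparison side is either a canonical drug name or ``group<i>``
    (1-based control group). ``pooling_map`` optionally maps surface
    forms onto pooled keys before counting (off by default).
    """

    comparisons: tuple[tuple[str, str, str], ...]
    control_k: int = 4
    seed: int = 0
    test_config: TestConfig = field(default_factory=TestConfig)
    highlight_terms: frozenset[str] = frozenset()
    pooling_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "comparisons", tuple(tuple(c) for c in self.comparisons))
        object.__setattr__(self, "highlight_terms", frozenset(self.highlight_terms))
        if self.control_k < 1:
            raise ValueError("control_k must be >= 1")

    def validate(self, lexicon: DrugLexicon) -> None:
        for label, side_s, side_t in self.comparisons:
            for side in (side_s, side_t):
                idx = _group_index(side)
                if idx is not None:
                    if not 1 <= idx <= self.control_k:
                        raise ValueError(f"{label}: control group index {idx} exceeds control_k")
                else:
                    lexicon.synonyms(side)  # raises on unknown drug

    @property
    def study_drugs(self) -> list[str]:
        drugs = []
        for _, side_s, side_t in self.comparisons:
            for side in (side_s, side_t):
                if _group_index(side) is None and side not in drugs:
                    drugs.append(side)
        return drugs

    def config_hash(self) -> str:
        payload = {
            "comparisons": [list(c) for c in self.comparisons],
            "control_k": self.control_k,
            "seed": self.seed,
            "test_config": asdict(self.test_config),
            "highlight_terms": sorted(self.highlight_terms),
            "pooling_map": dict(sorted(self.pooling_map.items())) if self.pooling_map else None,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_json(self, path) -> None:
        payload = {
            "comparisons": [list(c) for c in self.comparisons],
            "control_k": self.control_k,
            "seed": self.seed,
            "test_config": asdict(self.test_config),
            "highlight_terms": sorted(self.highlight_terms),
            "pooling_map": dict(self.pooling_map) if self.pooling_map else None,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "StudyPlan":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            comparisons=tuple(tuple(c) for c in payload["comparisons"]),
            control_k=payload.get("control_k", 4),
            seed=payload.get("seed", 0),
            test_config=TestConfig(**payload.get("test_config", {})),
            highlight_terms=frozenset(payload.get("highlight_terms") or ()),
            pooling_map=payload.get("pooling_map"),
        )


def _group_index(side: str) -> int | None:
    if side.startswith("group") and side[5:].isdigit():
        return int(side[5:])
    return None


def default_study_plan(seed: int = 0, test_config: TestConfig | None = None) -> StudyPlan:
    """The six-comparison design: validation drugs against each other and
    their control groups, then the two CGRP monoclonals against their
    control groups and head-to-head."""
    return StudyPlan(
        comparisons=(
            ("topiramate_vs_propranolol", "topiramate", "propranolol"),
            ("propranolol_vs_group1", "propranolol", "group1"),
            ("topiramate_vs_group2", "topiramate", "group2"),
            ("erenumab_vs_group3", "erenumab", "group3"),
            ("fremanezumab_vs_group4", "fremanezumab", "group4"),
            ("erenumab_vs_fremanezumab", "erenumab", "fremanezumab"),
        ),
        seed=seed,
        test_config=test_config or TestConfig(),
    )


def _round_half_up(value: Decimal, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


def corpus_summary(
    assignment: CorpusAssignment, total_posts: int, decimals: int = 2
) -> pd.DataFrame:
    """Per-drug post counts and percentage of the total collection.

    Percentages are rounded half-up to ``decimals`` places.
    """
    if total_posts <= 0:
        raise ValueError("total_posts must be positive")
    rows = []
    for drug in sorted(assignment.drug_corpora):
        count = len(assignment.drug_corpora[drug])
        pct = _round_half_up(Decimal(count) * 100 / Decimal(total_posts), decimals)
        rows.append({"drug": drug, "count": count, "percent": pct})
    return pd.DataFrame(rows, columns=["drug", "count", "percent"])


@dataclass
class HighlightReport:
    """Retained keywords annotated against a highlight dictionary."""

    table: pd.DataFrame  # word, rank, flagged
    n_flagged: int


def highlight_report(result: ComparisonResult, highlight_terms: Iterable[str]) -> HighlightReport:
    terms = set(highlight_terms)
    words = result.retained
    flagged = [w in terms for w in words]
    table = pd.DataFrame(
        {"word": words, "rank": range(1, len(words) + 1), "flagged": flagged}
    )
    return HighlightReport(table=table, n_flagged=int(sum(flagged)))


@dataclass
class StudyReport:
    """All comparison results, the corpus summary, and run metadata."""

    results: dict[str, ComparisonResult]
    failures: dict[str, str]
    summary: pd.DataFrame
    assignment: CorpusAssignment
    metadata: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for label, result in self.results.items():
            result.to_tsv(outdir / f"{label}.tsv")
            result.write_metadata(outdir / f"{label}.meta.json")
        self.summary.to_csv(outdir / "corpus_summary.tsv", sep="\t", index=False)
        self.assignment.to_json(outdir / "corpus_assignment.json")
        with open(outdir / "run_metadata.json", "w", encoding="utf-8") as fh:
            json.dump({**self.metadata, "failures": self.failures}, fh, indent=2, sort_keys=True)
        self._write_markdown(outdir / "report.md")

    def _write_markdown(self, path) -> None:
        lines = ["# Keyword comparison report", "", "## Corpus summary", ""]
        lines.append(self.summary.to_markdown(index=False))
        highlight = frozenset(self.metadata.get("highlight_terms", ()))
        for label, result in self.results.items():
            lines += ["", f"## {label}", ""]
            lines.append(
                f"{len(result.table)} words tested, "
                f"{int(result.table['significant'].sum())} significant, "
                f"{len(result.retained)} retained."
            )
            if result.retained:
                if highlight:
                    hl = highlight_report(result, highlight)
                    marked = [
                        f"**{w}**" if f else w
                        for w, f in zip(hl.table["word"], hl.table["flagged"])
                    ]
                    lines.append("")
                    lines.append(", ".join(marked))
                    lines.append("")
                    lines.append(f"{hl.n_flagged} highlighted term(s) in bold.")
                else:
                    lines.append("")
                    lines.append(", ".join(result.retained))
        for label, reason in self.failures.items():
            lines += ["", f"## {label}", "", f"FAILED: {reason}"]
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + "\n")


def run_study(
    posts: Sequence[Post],
    lexicon: DrugLexicon,
    plan: StudyPlan,
    date_start: int | None = None,
    date_end: int | None = None,
) -> StudyReport:
    """Execute a full study plan; deterministic given (posts, lexicon, plan)."""
    if not posts:
        raise ValueError("posts must be non-empty")
    plan.validate(lexicon)
    if date_start is not None or date_end is not None:
        lo = date_start if date_start is not None else min(p.timestamp for p in posts)
        hi = date_end if date_end is not None else max(p.timestamp for p in posts) + 1
        posts = filter_by_date(posts, lo, hi)
        log.info("date filter kept %d posts", len(posts))

    study_drugs = plan.study_drugs
    assignment = build_corpora(posts, lexicon, study_drugs)
    assignment.control_groups = partition_controls(
        assignment.control_pool, plan.control_k, plan.seed
    )
    assignment.seed = plan.seed
    log.info(
        "corpora: %s; control pool %d split into %s",
        {d: len(ids) for d, ids in assignment.drug_corpora.items()},
        len(assignment.control_pool),
        [len(g) for g in assignment.control_groups],
    )

    pooling = dict(plan.pooling_map) if plan.pooling_map else None
    tokenized: dict[str, TokenizedText] = {}
    for p in posts:
        toks = tokenize(p.text)
        if pooling:
            toks = [pooling.get(t, t) for t in toks]
        tokenized[p.post_id] = TokenizedText(p.post_id, toks)

    def resolve(side: str) -> set[str]:
        idx = _group_index(side)
        if idx is not None:
            return set(assignment.control_groups[idx - 1])
        return set(assignment.drug_corpora[side])

    results: dict[str, ComparisonResult] = {}
    failures: dict[str, str] = {}
    for label, side_s, side_t in plan.comparisons:
        ids_s, ids_t = resolve(side_s), resolve(side_t)
        drug_vs_drug = _group_index(side_s) is None and _group_index(side_t) is None
        if drug_vs_drug:
            n_shared = len(ids_s & ids_t)
            ids_s, ids_t = remove_shared(ids_s, ids_t)
            log.info("%s: removed %d shared posts from each side", label, n_shared)
        if not ids_s or not ids_t:
            reason = f"empty corpus for {side_s if not ids_s else side_t}"
            failures[label] = reason
            log.warning("%s failed: %s", label, reason)
            continue
        corpus_s = build_corpus(side_s, [tokenized[i] for i in sorted(ids_s)])
        corpus_t = build_corpus(side_t, [tokenized[i] for i in sorted(ids_t)])
        result = compare_corpora(corpus_s, corpus_t, plan.test_config)
        result.metadata.update({"label": label, "seed": plan.seed})
        results[label] = result
        log.info(
            "%s: %d words tested, %d significant, %d retained",
            label, len(result.table), int(result.table["significant"].sum()),
            len(result.retained),
        )

    summary = corpus_summary(assignment, total_posts=len(posts), decimals=2)
    metadata = {
        "n_posts": len(posts),
        "seed": plan.seed,
        "control_k": plan.control_k,
        "config_hash": plan.config_hash(),
        "test_config": asdict(plan.test_config),
        "highlight_terms": sorted(plan.highlight_terms),
        "date_start": date_start,
        "date_end": date_end,
    }
    return StudyReport(
        results=results,
        failures=failures,
        summary=summary,
        assignment=assignment,
        metadata=metadata,
    )
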