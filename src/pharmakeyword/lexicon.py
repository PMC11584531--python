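"""Drug lexicon, corpus assembly, control partitioning.

A drug corpus is the set of posts whose text mentions any brand or
generic synonym of the drug as a whole token — maximal runs of letters
and digits, so a fused dose such as "topamax50" does not count. The control pool is every post mentioning no
study drug and no drug in the CGRP therapeutic class, randomly split
into k groups by assigning each post an independent uniform digit in
1..k from a seeded generator. Posts shared between two compared drug
corpora are removed from both before testing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ingest import Post
from .textproc import alnum_runs

__all__ = [
    "DrugLexicon",
    "CorpusAssignment",
    "default_lexicon",
    "mentions_drug",
    "build_corpora",
    "partition_controls",
    "remove_shared",
]


@dataclass(frozen=True)
class DrugLexicon:
    """Canonical drug name -> lowercase synonym set, with a CGRP-class flag.

    ``cgrp_class`` names the drugs that count as CGRP therapeutics for
    control-pool exclusion (whether or not they are study drugs).
    """

    entries: Mapping[str, frozenset[str]]
    cgrp_class: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        entries = {k: frozenset(v) for k, v in self.entries.items()}
        object.__setattr__(self, "entries", entries)
        object.__setattr__(self, "cgrp_class", frozenset(self.cgrp_class))
        seen: dict[str, str] = {}
        for drug, synonyms in entries.items():
            if not synonyms:
                raise ValueError(f"drug {drug!r} has an empty synonym set")
            for s in synonyms:
                if s != s.lower() or len(s) < 3:
                    raise ValueError(f"synonym {s!r} of {drug!r} must be lowercase and >=3 chars")
                if s in seen:
                    raise ValueError(f"synonym {s!r} shared by {seen[s]!r} and {drug!r}")
                seen[s] = drug
        unknown = self.cgrp_class - set(entries)
        if unknown:
            raise ValueError(f"cgrp_class names not in lexicon: {sorted(unknown)}")

    def synonyms(self, drug: str) -> frozenset[str]:
        try:
            return self.entries[drug]
        except KeyError:
            raise ValueError(f"unknown drug {drug!r}") from None

    @property
    def drugs(self) -> list[str]:
        return sorted(self.entries)

    def to_json(self, path) -> None:
        payload = {
            drug: {"synonyms": sorted(syns), "cgrp": drug in self.cgrp_class}
            for drug, syns in sorted(self.entries.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DrugLexicon":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        entries = {drug: frozenset(spec["synonyms"]) for drug, spec in payload.items()}
        cgrp = frozenset(drug for drug, spec in payload.items() if spec.get("cgrp", False))
        return cls(entries=entries, cgrp_class=cgrp)


def default_lexicon() -> DrugLexicon:
    """Migraine-preventive lexicon used throughout the study design.

    Includes the intentional misspelling "propanolol" (common in posts)
    and two CGRP monoclonals (galcanezumab, eptinezumab) that are not
    study drugs but are excluded from the control pool as CGRP
    therapeutics.
    """
    return DrugLexicon(
        entries={
            "propranolol": frozenset({"propranolol", "inderal", "propanolol"}),
            "topiramate": frozenset({"topiramate", "topamax", "trokendi"}),
            "erenumab": frozenset({"erenumab", "aimovig"}),
            "fremanezumab": frozenset({"fremanezumab", "ajovy"}),
            "galcanezumab": frozenset({"galcanezumab", "emgality"}),
            "eptinezumab": frozenset({"eptinezumab", "vyepti"}),
        },
        cgrp_class=frozenset({"erenumab", "fremanezumab", "galcanezumab", "eptinezumab"}),
    )


@dataclass
class CorpusAssignment:
    """Post-id level result of corpus assembly and control partitioning."""

    drug_corpora: dict[str, set[str]]
    control_pool: set[str]
    control_groups: list[set[str]] = field(default_factory=list)
    seed: int | None = None

    def to_json(self, path) -> None:
        payload = {
            "drug_corpora": {d: sorted(ids) for d, ids in sorted(self.drug_corpora.items())},
            "control_pool": sorted(self.control_pool),
            "control_groups": [sorted(g) for g in self.control_groups],
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


def mentions_drug(post: Post, synonyms: Iterable[str]) -> bool:
    """True iff any synonym occurs in the post text as a whole token."""
    synonyms = set(synonyms)
    if not synonyms:
        raise ValueError("empty synonym set")
    return not synonyms.isdisjoint(alnum_runs(post.text))


def build_corpora(
    posts: Sequence[Post],
    lexicon: DrugLexicon,
    study_drugs: Sequence[str],
) -> CorpusAssignment:
    """Assemble per-drug corpora and the control pool (groups not yet drawn).

    A post lands in every study drug corpus whose synonyms it mentions
    (overlaps are resolved later by :func:`remove_shared`). Controls
    are posts mentioning no study-drug synonym and no synonym of any
    drug in the lexicon's CGRP class.
    """
    for drug in study_drugs:
        lexicon.synonyms(drug)  # raises on unknown drug

    excluded_drugs = set(study_drugs) | set(lexicon.cgrp_class)
    syn_to_drug = {
        s: drug for drug in excluded_drugs for s in lexicon.synonyms(drug)
    }

    drug_corpora: dict[str, set[str]] = {d: set() for d in study_drugs}
    control_pool: set[str] = set()
    for post in posts:
        hits = {syn_to_drug[t] for t in set(alnum_runs(post.text)) if t in syn_to_drug}
        if not hits:
            control_pool.add(post.post_id)
            continue
        for drug in hits & set(study_drugs):
            drug_corpora[drug].add(post.post_id)
    return CorpusAssignment(drug_corpora=drug_corpora, control_pool=control_pool)


def partition_controls(control_pool: Iterable[str], k: int, seed: int) -> list[set[str]]:
    """Assign each control post an independent uniform digit in 1..k.

    Deterministic given the seed and the pool's contents (ids are
    processed in sorted order, so input ordering is irrelevant).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ids = sorted(control_pool)
    rng = np.random.default_rng(seed)
    digits = rng.integers(1, k + 1, size=len(ids))
    groups: list[set[str]] = [set() for _ in range(k)]
    for post_id, digit in zip(ids, digits):
        groups[digit - 1].add(post_id)
    return groups


def remove_shared(corpus_a: set[str], corpus_b: set[str]) -> tuple[set[str], set[str]]:
    """Drop posts present in both corpora from both; outputs are disjoint."""
    shared = corpus_a & corpus_b
    return corpus_a - shared, corpus_b - shared
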