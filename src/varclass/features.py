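"""Mutation Collection construction, binary encoding and dataset splits.

The Mutation Collection is the ranked reference panel of variant sites that
defines the classifier's feature dimensions: sites are ranked by the number of
distinct cohort samples that carry them, high to low, with ties broken by
genomic order so the ranking is deterministic.  Two selection rules are
supported: ``top_k`` (keep the k most frequent sites) and ``min_occurrence``
(keep sites carried by strictly more than m samples — the rule used for the
pooled cancer-vs-healthy and multi-cancer models).

A sample encodes against a collection as a 0/1 vector: position j is 1 iff the
sample carries collection site j.  Labels are one-hot over a fixed class order.
"""

from __future__ import annotations

import hashlib
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import VariantKey, VariantProfile

logger = logging.getLogger("varclass")


@dataclass
class MutationCollection:
    """Ordered reference panel of variant sites with occurrence counts."""

    sites: list[VariantKey]
    counts: np.ndarray  # per-site number of distinct source-cohort samples
    provenance: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.sites) != len(self.counts):
            raise ValueError("sites and counts length mismatch")
        if len(self.sites) != len(set(self.sites)):
            raise ValueError("collection sites must be unique")
        if len(self.counts) and (np.diff(self.counts) > 0).any():
            raise ValueError("counts must be non-increasing along sites")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def fingerprint(self) -> str:
        """Stable hash of the ordered site list, for model/data compatibility checks."""
        h = hashlib.sha256()
        for s in self.sites:
            h.update(str(s).encode())
        return h.hexdigest()[:16]

    def index(self) -> dict[VariantKey, int]:
        return {site: j for j, site in enumerate(self.sites)}

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# provenance: {self.provenance}\n")
            fh.write("chrom\tpos\tref\talt\tcount\n")
            for site, n in zip(self.sites, self.counts):
                fh.write(f"{site.chrom}\t{site.pos}\t{site.ref}\t{site.alt}\t{n}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MutationCollection":
        sites, counts = [], []
        provenance = ""
        with open(path) as fh:
            for line in fh:
                if line.startswith("# provenance:"):
                    provenance = line.split(":", 1)[1].strip()
                    continue
                if line.startswith("#") or line.startswith("chrom\t") or not line.strip():
                    continue
                c, p, r, a, n = line.rstrip("\n").split("\t")
                sites.append(VariantKey.make(c, int(p), r, a))
                counts.append(int(n))
        return cls(sites, np.asarray(counts), provenance)


def build_collection(profiles: Sequence[VariantProfile], *,
                     top_k: int | None = None,
                     min_occurrence: int | None = None) -> MutationCollection:
    """Rank every site seen in ``profiles`` by sample occurrence and select.

    Exactly one of ``top_k`` (keep the k highest-ranked sites) and
    ``min_occurrence`` (keep sites with count strictly greater than m) must be
    given.  The occurrence count of a site is the number of distinct profiles
    containing it; ties in count are broken by genomic order.
    """
    if not profiles:
        raise ValueError("cannot build a collection from an empty cohort")
    if (top_k is None) == (min_occurrence is None):
        raise ValueError("give exactly one of top_k or min_occurrence")
    if top_k is not None and top_k < 1:
        raise ValueError(f"top_k must be >= 1, got {top_k}")
    if min_occurrence is not None and min_occurrence < 0:
        raise ValueError(f"min_occurrence must be >= 0, got {min_occurrence}")

    counter: Counter[VariantKey] = Counter()
    for prof in profiles:
        counter.update(prof.variants)
    ranked = sorted(counter.items(), key=lambda it: (-it[1], it[0].sort_key))

    if top_k is not None:
        if top_k > len(ranked):
            logger.warning("top_k=%d exceeds %d available sites; keeping all", top_k, len(ranked))
        kept = ranked[:top_k]
        provenance = f"top_k={top_k} from {len(profiles)} profiles"
    else:
        kept = [(s, n) for s, n in ranked if n > min_occurrence]
        provenance = f"min_occurrence>{min_occurrence} from {len(profiles)} profiles"
    sites = [s for s, _ in kept]
    counts = np.array([n for _, n in kept], dtype=np.int64)
    return MutationCollection(sites, counts, provenance)


def encode(profile: VariantProfile, collection: MutationCollection) -> np.ndarray:
    """Binary feature vector: element j is 1 iff collection site j ∈ profile."""
    if len(collection) == 0:
        raise ValueError("cannot encode against an empty collection")
    x = np.fromiter((1 if s in profile.variants else 0 for s in collection.sites),
                    dtype=np.uint8, count=len(collection))
    if not x.any():
        logger.warning("sample %s shares no sites with the collection (all-zero row)",
                       profile.sample_id)
    return x


def one_hot(label: str, classes: Sequence[str]) -> np.ndarray:
    if label not in classes:
        raise ValueError(f"label {label!r} not in classes {list(classes)}")
    y = np.zeros(len(classes), dtype=np.float64)
    y[list(classes).index(label)] = 1.0
    return y


@dataclass
class EncodedDataset:
    """Binary feature matrix X, one-hot label matrix Y and their row/column maps."""

    X: np.ndarray
    Y: np.ndarray
    sample_ids: list[str]
    classes: list[str]
    collection: MutationCollection

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.Y = np.asarray(self.Y, dtype=np.float64)
        if self.X.shape[0] != self.Y.shape[0] or self.X.shape[0] != len(self.sample_ids):
            raise ValueError("row count mismatch between X, Y and sample_ids")
        if self.X.shape[1] != len(self.collection):
            raise ValueError("X column count does not match collection size")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("X must be a 0/1 matrix")
        if not np.allclose(self.Y.sum(axis=1), 1.0):
            raise ValueError("every row of Y must sum to 1")

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def labels(self) -> np.ndarray:
        """Integer class index per row."""
        return self.Y.argmax(axis=1)


def encode_cohort(profiles: Sequence[VariantProfile], collection: MutationCollection,
                  classes: Sequence[str] | None = None) -> EncodedDataset:
    """Encode a list of profiles into an EncodedDataset (rows in input order)."""
    if classes is None:
        seen: dict[str, None] = {}
        for p in profiles:
            seen.setdefault(p.label, None)
        classes = list(seen)
    X = np.vstack([encode(p, collection) for p in profiles])
    Y = np.vstack([one_hot(p.label, classes) for p in profiles])
    return EncodedDataset(X, Y, [p.sample_id for p in profiles], list(classes), collection)


@dataclass
class SplitIndex:
    """Stratified train/test row partition, reproducible from its seed."""

    train_rows: list[int]
    test_rows: list[int]
    seed: int
    fraction: float

    def __post_init__(self) -> None:
        overlap = set(self.train_rows) & set(self.test_rows)
        if overlap:
            raise ValueError(f"train/test rows overlap: {sorted(overlap)[:5]}")


def split_dataset(data: EncodedDataset, fraction: float = 0.8, seed: int = 0) -> SplitIndex:
    """Stratified split: per class, round(fraction × n) rows go to train.

    The per-class train count is clamped to [1, n−1] so both halves are
    non-empty; shuffling is driven solely by ``seed``.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    labels = data.labels()
    train_rows: list[int] = []
    test_rows: list[int] = []
    for ci, cname in enumerate(data.classes):
        rows = np.flatnonzero(labels == ci)
        if len(rows) == 0:
            continue
        if len(rows) < 2:
            raise ValueError(f"class {cname!r} has fewer than 2 samples; cannot split")
        rows = rng.permutation(rows)
        n_train = int(round(fraction * len(rows)))
        n_train = min(max(n_train, 1), len(rows) - 1)
        train_rows.extend(int(r) for r in rows[:n_train])
        test_rows.extend(int(r) for r in rows[n_train:])
    return SplitIndex(sorted(train_rows), sorted(test_rows), seed, fraction)


def assemble_binary_task(case_profiles: Sequence[VariantProfile],
                         control_profiles: Sequence[VariantProfile],
                         collection: MutationCollection,
                         case_label: str | None = None,
                         control_label: str | None = None) -> EncodedDataset:
    """Two-class dataset (case first) encoded against a case-derived collection.

    Control samples sharing no collection sites encode to all-zero rows and are
    retained — control-private sites never become feature columns.
    """
    if not case_profiles or not control_profiles:
        raise ValueError("both case and control cohorts must be non-empty")
    dup = {p.sample_id for p in case_profiles} & {p.sample_id for p in control_profiles}
    if dup:
        raise ValueError(f"sample_id(s) appear in both cohorts: {sorted(dup)[:5]}")

    def _infer(profiles: Sequence[VariantProfile], given: str | None, role: str) -> str:
        if given is not None:
            return given
        labs = {p.label for p in profiles}
        if len(labs) > 1:
            raise ValueError(f"{role} cohort has mixed labels {sorted(labs)}; pass an explicit label")
        return next(iter(labs))

    case_label = _infer(case_profiles, case_label, "case")
    control_label = _infer(control_profiles, control_label, "control")
    relabelled = (
        [VariantProfile(p.sample_id, case_label, p.variants) for p in case_profiles]
        + [VariantProfile(p.sample_id, control_label, p.variants) for p in control_profiles]
    )
    return encode_cohort(relabelled, collection, classes=[case_label, control_label])
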