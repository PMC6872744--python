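"""Synthetic cohort generator with planted per-class signature sites.

The generator emulates the statistical structure the classifier assumes in
real tumor cohorts: every cancer-like class owns a set of recurrent
"signature" variant sites that its samples carry with high probability
(penetrance), on top of a long tail of low-frequency background sites shared
by everyone; healthy samples draw from the background only.  Pairs of classes
may share a configured fraction of their signature sites, mimicking the
molecular similarity that makes some cancer pairs hard to separate.

All sites are independent Bernoulli draws — no linkage or trinucleotide
context — because the downstream encoding treats sites independently anyway.
Coordinates are synthetic but valid: 22 autosomes, positions spaced 100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .variants import CohortManifest, VariantKey, VariantProfile, write_minimal_vcf

#: the 12 tumor-class names used by the default cohort, plus a healthy class
DEFAULT_CLASSES = ["BLCA", "BRCA", "COAD", "GBM", "KIRC", "LGG",
                   "LUSC", "OV", "PRAD", "SKCM", "THCA", "UCEC"]
HEALTHY = "HEALTHY"

#: default signature sharing, shaped like the observed sharing hierarchy among
#: uterine, colon and breast tumors (one dominant pair, two lesser ones)
DEFAULT_OVERLAP = {("UCEC", "COAD"): 0.7, ("UCEC", "BRCA"): 0.2, ("BRCA", "COAD"): 0.1}

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Cohort generator settings; defaults define the standard study conditions."""

    classes: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    healthy_class: str = HEALTHY
    n_per_class: int = 100
    n_healthy: int = 100
    n_signature: int = 200
    penetrance: float = 0.9
    n_background: int = 5000
    bg_rate: float = 0.02
    signature_overlap: dict[tuple[str, str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.signature_overlap is None:
            # the default sharing structure only applies to the default classes
            self.signature_overlap = (dict(DEFAULT_OVERLAP)
                                      if self.classes == DEFAULT_CLASSES else {})
        if len(set(self.classes)) != len(self.classes) or self.healthy_class in self.classes:
            raise ValueError("class names must be unique and distinct from the healthy class")
        for p, name in ((self.penetrance, "penetrance"), (self.bg_rate, "bg_rate")):
            if not 0 <= p <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if min(self.n_per_class, self.n_healthy, self.n_signature, self.n_background) < 0:
            raise ValueError("counts must be >= 0")
        for (a, b), f in self.signature_overlap.items():
            if a == b or a not in self.classes or b not in self.classes:
                raise ValueError(f"overlap pair ({a}, {b}) must name two distinct classes")
            if not 0 <= f <= 1:
                raise ValueError(f"overlap fraction for ({a}, {b}) must be in [0, 1], got {f}")


@dataclass
class SimTruth:
    """Ground truth: each class's signature sites and each sample's label."""

    signatures: dict[str, set[VariantKey]]
    labels: dict[str, str]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("class\tchrom\tpos\tref\talt\n")
            for cname, sites in self.signatures.items():
                for s in sorted(sites, key=lambda k: k.sort_key):
                    fh.write(f"{cname}\t{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\n")


def _site_universe(n: int, rng: np.random.Generator) -> list[VariantKey]:
    """n distinct SNV keys on autosomes 1..22, positions spaced 100 bp."""
    refs = rng.integers(0, 4, size=n)
    shifts = rng.integers(1, 4, size=n)  # alt = ref shifted by 1..3, never equal
    return [
        VariantKey(str(i % 22 + 1), 1000 + 100 * (i // 22),
                   _BASES[refs[i]], _BASES[(refs[i] + shifts[i]) % 4])
        for i in range(n)
    ]


def _allocate_signatures(cfg: SimConfig, pool: list[list[VariantKey]]
                         ) -> dict[str, list[VariantKey]]:
    """Assign signature site lists honouring pairwise overlap fractions exactly.

    Each class starts with its own fresh sites.  For a pair (a, b) with
    fraction f, round(f·n_signature) sites are lent from one class's unlent
    head region into the other's tail region, so every configured pair shares
    exactly its rounded count and unconfigured pairs stay disjoint.
    """
    n = cfg.n_signature
    sig = {c: list(pool[i]) for i, c in enumerate(cfg.classes)}
    lend_ptr = {c: 0 for c in cfg.classes}   # head region: own sites lent out
    repl_ptr = {c: 0 for c in cfg.classes}   # tail region: sites replaced by borrowed ones
    for (a, b), f in cfg.signature_overlap.items():
        s = int(round(f * n))
        if s == 0:
            continue
        for lender, borrower in ((a, b), (b, a)):
            lend_ok = lend_ptr[lender] + s + repl_ptr[lender] <= n
            borrow_ok = lend_ptr[borrower] + repl_ptr[borrower] + s <= n
            if lend_ok and borrow_ok:
                shared = sig[lender][lend_ptr[lender]:lend_ptr[lender] + s]
                lend_ptr[lender] += s
                start = n - repl_ptr[borrower] - s
                sig[borrower][start:start + s] = shared
                repl_ptr[borrower] += s
                break
        else:
            raise ValueError(f"overlap fractions over-constrain pair ({a}, {b})")
    return sig


def simulate_cohort(cfg: SimConfig) -> tuple[list[VariantProfile], SimTruth]:
    """Draw a full cohort; reproducible from ``cfg.seed`` alone."""
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.classes)
    universe = _site_universe(cfg.n_background + n_classes * cfg.n_signature, rng)
    bg_sites = universe[:cfg.n_background]
    pool = [universe[cfg.n_background + i * cfg.n_signature:
                     cfg.n_background + (i + 1) * cfg.n_signature]
            for i in range(n_classes)]
    sig = _allocate_signatures(cfg, pool)

    profiles: list[VariantProfile] = []
    labels: dict[str, str] = {}
    bg_arr = np.array(bg_sites, dtype=object)
    for cname in cfg.classes:
        sig_arr = np.array(sig[cname], dtype=object)
        carry_sig = rng.random((cfg.n_per_class, len(sig_arr))) < cfg.penetrance
        carry_bg = rng.random((cfg.n_per_class, cfg.n_background)) < cfg.bg_rate
        for k in range(cfg.n_per_class):
            sid = f"{cname}_{k:04d}"
            variants = frozenset(sig_arr[carry_sig[k]]) | frozenset(bg_arr[carry_bg[k]])
            profiles.append(VariantProfile(sid, cname, variants))
            labels[sid] = cname
    carry_bg = rng.random((cfg.n_healthy, cfg.n_background)) < cfg.bg_rate
    for k in range(cfg.n_healthy):
        sid = f"{cfg.healthy_class}_{k:04d}"
        profiles.append(VariantProfile(sid, cfg.healthy_class, frozenset(bg_arr[carry_bg[k]])))
        labels[sid] = cfg.healthy_class

    truth = SimTruth({c: set(sig[c]) for c in cfg.classes}, labels)
    return profiles, truth


def write_cohort(profiles: Sequence[VariantProfile], truth: SimTruth,
                 out_dir: str | Path) -> CohortManifest:
    """Write one minimal VCF per sample plus manifest and truth TSVs.

    VCF bodies are deterministic (sites in genomic order), so identical seeds
    produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = [str(i) for i in range(1, 23)]
    entries = []
    for prof in profiles:
        vcf_path = out_dir / f"{prof.sample_id}.vcf"
        write_minimal_vcf(prof.variants, vcf_path, contigs=contigs)
        entries.append((prof.sample_id, Path(vcf_path.name), prof.label))
    seen: dict[str, None] = {}
    for prof in profiles:
        seen.setdefault(prof.label, None)
    manifest = CohortManifest([(sid, out_dir / p, lab) for sid, p, lab in entries],
                              classes=list(seen))
    with open(out_dir / "manifest.tsv", "w") as fh:
        fh.write("sample_id\tpath\tlabel\n")
        for sid, p, lab in entries:
            fh.write(f"{sid}\t{p}\t{lab}\n")  # paths relative to the manifest
    truth.to_tsv(out_dir / "truth.tsv")
    return manifest
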