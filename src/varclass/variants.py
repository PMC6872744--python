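"""Per-sample variant files and cohort manifests.

A sample is represented by the set of point mutations it carries.  Variant
identity is the exact tuple (normalized chromosome, 1-based position, ref,
alt): no left-alignment or indel normalization is attempted, and genotype
fields are ignored — the presence of a record means the sample carries the
variant.  Multi-allelic records are split into one key per alternate allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pysam

logger = logging.getLogger("varclass")

_ALLELE_CHARS = frozenset("ACGTN")

#: chromosomes get natural order: 1..22 numerically, then X, Y, MT, then others
_SPECIAL_CHROM_RANK = {"X": 23, "Y": 24, "MT": 25, "M": 25}


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr`` prefix so ``chr17`` and ``17`` compare equal."""
    c = chrom.strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    return c.upper() if c.upper() in _SPECIAL_CHROM_RANK else c


def chrom_sort_key(chrom: str) -> tuple:
    if chrom.isdigit():
        return (0, int(chrom), "")
    return (1, _SPECIAL_CHROM_RANK.get(chrom, 99), chrom)


@dataclass(frozen=True)
class VariantKey:
    """Identity of one point mutation: (chrom, pos, ref, alt), one alt only."""

    chrom: str
    pos: int
    ref: str
    alt: str

    @classmethod
    def make(cls, chrom: str, pos: int, ref: str, alt: str) -> "VariantKey":
        """Build a normalized, validated key."""
        chrom = normalize_chrom(str(chrom))
        ref = ref.upper()
        alt = alt.upper()
        if pos < 1:
            raise ValueError(f"position must be >= 1, got {pos}")
        if not ref or not set(ref) <= _ALLELE_CHARS:
            raise ValueError(f"invalid ref allele {ref!r}")
        if not alt or not set(alt) <= _ALLELE_CHARS:
            raise ValueError(f"invalid alt allele {alt!r}")
        return cls(chrom, int(pos), ref, alt)

    @property
    def sort_key(self) -> tuple:
        """Genomic order: chromosome (natural), position, ref, alt."""
        return (*chrom_sort_key(self.chrom), self.pos, self.ref, self.alt)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantProfile:
    """One sample: its class label and the set of variants it carries."""

    sample_id: str
    label: str
    variants: frozenset[VariantKey]


@dataclass
class CohortManifest:
    """Sample → (file, label) table; ``classes`` order fixes one-hot indices."""

    entries: list[tuple[str, Path, str]]
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [sid for sid, _, _ in self.entries]
        dupes = {s for s in ids if ids.count(s) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in manifest: {sorted(dupes)}")
        if not self.classes:
            seen: dict[str, None] = {}
            for _, _, lab in self.entries:
                seen.setdefault(lab, None)
            self.classes = list(seen)
        bad = [lab for _, _, lab in self.entries if lab not in self.classes]
        if bad:
            raise ValueError(f"labels outside declared class vocabulary: {sorted(set(bad))}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CohortManifest":
        """Read a headered TSV with columns sample_id, path, label.

        Relative file paths are resolved against the manifest's directory.
        """
        path = Path(path)
        entries: list[tuple[str, Path, str]] = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            try:
                i_s, i_p, i_l = (header.index(c) for c in ("sample_id", "path", "label"))
            except ValueError as exc:
                raise ValueError(f"{path}: manifest header must contain sample_id, path, label") from exc
            for line in fh:
                if not line.strip():
                    continue
                row = line.rstrip("\n").split("\t")
                p = Path(row[i_p])
                if not p.is_absolute():
                    p = path.parent / p
                entries.append((row[i_s], p, row[i_l]))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("sample_id\tpath\tlabel\n")
            for sid, p, lab in self.entries:
                fh.write(f"{sid}\t{p}\t{lab}\n")


def read_variant_file(path: str | Path, pass_only: bool = True) -> set[VariantKey]:
    """Read a VCF 4.x file (plain or bgzipped) into a set of variant keys.

    One key per (record, alt) pair; multi-allelic records split.  Records whose
    FILTER is neither PASS nor missing are dropped when ``pass_only`` (the
    default).  Symbolic or breakend alts are skipped with a counted warning.
    """
    path = Path(path)
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"cannot parse VCF {path}: {exc}") from exc
    keys: set[VariantKey] = set()
    n_symbolic = n_filtered = n_records = 0
    with vf:
        for rec in vf:
            n_records += 1
            if pass_only:
                filters = list(rec.filter.keys())
                if filters and filters != ["PASS"]:
                    n_filtered += 1
                    continue
            for alt in rec.alts or ():
                if alt is None or any(c in alt for c in "<>[].*"):
                    n_symbolic += 1
                    continue
                try:
                    keys.add(VariantKey.make(rec.chrom, rec.pos, rec.ref, alt))
                except ValueError:
                    n_symbolic += 1
    if n_symbolic:
        logger.warning("%s: skipped %d symbolic/invalid alt allele(s)", path.name, n_symbolic)
    if n_records == 0:
        logger.warning("%s: VCF contains no data lines", path.name)
    return keys


def load_cohort(manifest: CohortManifest, pass_only: bool = True) -> list[VariantProfile]:
    """Load one profile per manifest entry, in manifest order."""
    missing = [(sid, p) for sid, p, _ in manifest.entries if not Path(p).exists()]
    if missing:
        sid, p = missing[0]
        raise FileNotFoundError(f"variant file for sample {sid!r} not found: {p}")
    profiles = [
        VariantProfile(sid, lab, frozenset(read_variant_file(p, pass_only=pass_only)))
        for sid, p, lab in manifest.entries
    ]
    per_class: dict[str, int] = {}
    for prof in profiles:
        per_class[prof.label] = per_class.get(prof.label, 0) + 1
    logger.info("loaded cohort: %s", ", ".join(f"{k}={v}" for k, v in per_class.items()))
    return profiles


def write_variants_tsv(variants: Iterable[VariantKey], path: str | Path) -> None:
    """Write a normalized variant list as TSV (chrom, pos, ref, alt)."""
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for v in sorted(variants, key=lambda k: k.sort_key):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\n")


def write_minimal_vcf(variants: Iterable[VariantKey], path: str | Path,
                      contigs: Sequence[str] | None = None) -> None:
    """Write variants as a minimal VCF 4.2 file (sites only, FILTER=PASS)."""
    keys = sorted(variants, key=lambda k: k.sort_key)
    if contigs is None:
        seen: dict[str, None] = {}
        for k in keys:
            seen.setdefault(k.chrom, None)
        contigs = sorted(seen, key=chrom_sort_key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FILTER=<ID=PASS,Description="All filters passed">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for k in keys:
            fh.write(f"{k.chrom}\t{k.pos}\t.\t{k.ref}\t{k.alt}\t.\tPASS\t.\n")
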