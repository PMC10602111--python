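"""Domain types and text-format readers/writers for GWAS summary data.

Every other module consumes the types defined here: variants, per-study
association statistics, LD reference panels, genomic interval annotations,
and individual-level cohort tables.

Conventions
-----------
* Variant positions are 1-based; the genome build is opaque metadata.
* Interval annotations use the BED convention (0-based, half-open) and are
  converted to variant coordinates only inside :meth:`AnnotationSet.contains`.
* Summary statistics, intervals, dosages, and cohorts are plain delimited
  text with headers, so that a write followed by a read round-trips exactly
  to printed precision.
"""

from __future__ import annotations

import math
import sys
import logging
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("t2dclust")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

_VALID_BASES = frozenset("ACGT")

ANCESTRY_TAGS = ("AFR", "AMR", "EAS", "EUR", "SAS", "MULTI")
SEX_TAGS = ("female", "male", "combined")


class FormatError(ValueError):
    """A file-level problem: missing columns, undecodable layout."""


class RowError(ValueError):
    """A row-level problem; carries the 1-based line number when known."""


@dataclass(frozen=True)
class VariantKey:
    """A biallelic (or indel) variant identified by position and alleles.

    Equality and hashing are order-insensitive in ``(allele1, allele2)``
    and ignore ``rsid``: the same site read from two files with swapped
    allele columns compares equal.
    """

    chrom: str
    pos: int
    allele1: str
    allele2: str
    rsid: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "allele1", self.allele1.upper())
        object.__setattr__(self, "allele2", self.allele2.upper())
        for a in (self.allele1, self.allele2):
            if not a or not set(a) <= _VALID_BASES:
                raise ValueError(f"invalid allele {a!r} at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"position must be 1-based positive, got {self.pos}")

    @property
    def alleles(self) -> tuple[str, str]:
        return tuple(sorted((self.allele1, self.allele2)))

    @property
    def is_indel(self) -> bool:
        return len(self.allele1) > 1 or len(self.allele2) > 1

    @property
    def is_strand_ambiguous(self) -> bool:
        """A/T or C/G SNVs cannot be strand-resolved from alleles alone."""
        return self.alleles in (("A", "T"), ("C", "G"))

    @property
    def vid(self) -> str:
        """Canonical string id (chrom:pos:sorted alleles)."""
        return f"{self.chrom}:{self.pos}:{self.alleles[0]}:{self.alleles[1]}"

    def other_allele(self, allele: str) -> str:
        if allele == self.allele1:
            return self.allele2
        if allele == self.allele2:
            return self.allele1
        raise ValueError(f"{allele} is not an allele of {self.vid}")

    def __eq__(self, other):
        if not isinstance(other, VariantKey):
            return NotImplemented
        return (self.chrom, self.pos, self.alleles) == (other.chrom, other.pos, other.alleles)

    def __hash__(self):
        return hash((self.chrom, self.pos, self.alleles))


@dataclass(frozen=True)
class AssociationStat:
    """One variant's effect in one GWAS: the atom of summary-statistic work."""

    key: VariantKey
    effect_allele: str
    beta: float
    se: float
    p: float
    n: float | None = None
    eaf: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "effect_allele", self.effect_allele.upper())
        if self.effect_allele not in (self.key.allele1, self.key.allele2):
            raise ValueError(
                f"effect allele {self.effect_allele} not in {self.key.vid}"
            )
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"se must be positive finite, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValueError(f"beta must be finite, got {self.beta}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p must lie in [0,1], got {self.p}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"eaf must lie in [0,1], got {self.eaf}")

    @property
    def z(self) -> float:
        return self.beta / self.se

    def flipped(self) -> "AssociationStat":
        """Re-express the effect on the other allele: beta and eaf flip, p does not."""
        return replace(
            self,
            effect_allele=self.key.other_allele(self.effect_allele),
            beta=-self.beta,
            eaf=None if self.eaf is None else 1.0 - self.eaf,
        )

    def aligned_to(self, allele: str) -> "AssociationStat":
        return self if self.effect_allele == allele else self.flipped()


@dataclass
class GwasStudy:
    """A set of per-variant association statistics for one trait GWAS."""

    trait_label: str
    ancestry_tag: str = "MULTI"
    sex_tag: str = "combined"
    stats: list[AssociationStat] = field(default_factory=list)

    def __post_init__(self):
        if self.ancestry_tag not in ANCESTRY_TAGS:
            raise ValueError(f"unknown ancestry tag {self.ancestry_tag}")
        if self.sex_tag not in SEX_TAGS:
            raise ValueError(f"unknown sex tag {self.sex_tag}")
        self._by_key = {s.key: s for s in self.stats}

    @property
    def label(self) -> str:
        """Trait label with the sex-stratified suffix convention (_F/_M)."""
        suffix = {"female": "_F", "male": "_M"}.get(self.sex_tag, "")
        return self.trait_label + suffix

    @property
    def median_n(self) -> float:
        ns = [s.n for s in self.stats if s.n is not None]
        return float(np.median(ns)) if ns else 0.0

    def get(self, key: VariantKey) -> AssociationStat | None:
        return self._by_key.get(key)

    def __contains__(self, key: VariantKey) -> bool:
        return key in self._by_key

    def __len__(self) -> int:
        return len(self.stats)


class LdPanel:
    """Pairwise LD (r-squared) and MAF lookup for one reference population.

    r2 is symmetric, r2(v, v) = 1, and absent pairs default to 0.
    """

    def __init__(self, population_tag: str):
        self.population_tag = population_tag
        self._r2: dict[frozenset, float] = {}
        self._maf: dict[VariantKey, float] = {}

    def set_r2(self, a: VariantKey, b: VariantKey, value: float) -> None:
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"r2 must lie in [0,1], got {value}")
        if a != b:
            self._r2[frozenset((a, b))] = value

    def r2(self, a: VariantKey, b: VariantKey) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def set_maf(self, v: VariantKey, maf: float) -> None:
        if not (0.0 <= maf <= 0.5):
            raise ValueError(f"MAF must lie in [0, 0.5], got {maf}")
        self._maf[v] = maf

    def maf(self, v: VariantKey) -> float | None:
        return self._maf.get(v)

    def pairs(self):
        for pair, value in self._r2.items():
            a, b = tuple(pair)
            yield a, b, value


class AnnotationSet:
    """Genomic intervals (0-based half-open) for one cell-type annotation."""

    def __init__(self, cell_type: str, intervals: Iterable[tuple[str, int, int]] = ()):
        self.cell_type = cell_type
        self.intervals: list[tuple[str, int, int]] = []
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if start >= end:
            raise RowError(f"interval start {start} >= end {end} on {chrom}")
        self.intervals.append((str(chrom), int(start), int(end)))
        self._index = None

    def __len__(self) -> int:
        return len(self.intervals)

    def _build_index(self):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in self.intervals:
            by_chrom.setdefault(chrom, []).append((start, end))
        self._index = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            # merge for the containment index only; stored intervals stay raw
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged])
            ends = np.array([m[1] for m in merged])
            self._index[chrom] = (starts, ends)

    def contains(self, chrom: str, pos: int) -> bool:
        """Whether 1-based position ``pos`` falls inside any interval."""
        if self._index is None:
            self._build_index()
        entry = self._index.get(str(chrom))
        if entry is None:
            return False
        starts, ends = entry
        zero_based = pos - 1  # single BED <-> variant coordinate conversion point
        i = bisect_right(starts, zero_based) - 1
        return i >= 0 and zero_based < ends[i]


@dataclass
class CohortTable:
    """Individual-level cohort data.

    ``samples`` is indexed by individual id and carries age, sex, bmi,
    t2d_status, hba1c_max, lipid_med, ancestry_label, principal components
    (``PC1``...), labs (``lab_<trait>``), and binary outcomes
    (``outcome_<name>``). ``dosages`` is individuals x variants (columns are
    canonical variant ids) counting the allele recorded in
    ``counted_alleles``; NaN marks a missing dosage.
    """

    samples: pd.DataFrame
    dosages: pd.DataFrame
    counted_alleles: dict[str, str] = field(default_factory=dict)
    variants: dict[str, VariantKey] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.dosages) and not self.dosages.index.equals(self.samples.index):
            raise ValueError("samples and dosages must be indexed identically")
        with np.errstate(invalid="ignore"):
            vals = self.dosages.to_numpy(dtype=float)
        if vals.size and np.nanmin(vals) < 0 or vals.size and np.nanmax(vals) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        if "bmi" in self.samples and (self.samples["bmi"].dropna() <= 0).any():
            raise ValueError("bmi must be positive when present")

    @property
    def n(self) -> int:
        return len(self.samples)

    def lab_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("lab_")]

    def outcome_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("outcome_")]

    def pc_columns(self) -> list[str]:
        return [c for c in self.samples.columns if c.startswith("PC")]


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

DEFAULT_SUMSTAT_DIALECT = {
    "chrom": "chrom",
    "pos": "pos",
    "allele1": "allele1",
    "allele2": "allele2",
    "effect_allele": "effect_allele",
    "beta": "beta",
    "se": "se",
    "p": "p",
    "n": "n",
    "eaf": "eaf",
    "rsid": "rsid",
}

_REQUIRED_SUMSTAT_FIELDS = ("chrom", "pos", "allele1", "allele2", "effect_allele", "beta", "se", "p")


def _read_table(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str)


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str | None = None,
    ancestry_tag: str = "MULTI",
    sex_tag: str = "combined",
    on_error: str = "fail",
) -> GwasStudy:
    """Read a delimited summary-statistics file into a :class:`GwasStudy`.

    ``dialect`` maps canonical field names to the file's column names;
    ``on_error`` is ``"fail"`` (default) or ``"skip"`` for malformed rows.
    """
    dialect = {**DEFAULT_SUMSTAT_DIALECT, **(dialect or {})}
    df = _read_table(path)
    missing = [f for f in _REQUIRED_SUMSTAT_FIELDS if dialect[f] not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    stats = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 = header
        rec = dict(zip(df.columns, row))
        try:
            key = VariantKey(
                chrom=str(rec[dialect["chrom"]]),
                pos=int(rec[dialect["pos"]]),
                allele1=str(rec[dialect["allele1"]]),
                allele2=str(rec[dialect["allele2"]]),
                rsid=(str(rec[dialect["rsid"]]) if dialect["rsid"] in rec and pd.notna(rec[dialect["rsid"]]) else None),
            )
            n_col, eaf_col = dialect["n"], dialect["eaf"]
            stats.append(
                AssociationStat(
                    key=key,
                    effect_allele=str(rec[dialect["effect_allele"]]),
                    beta=float(rec[dialect["beta"]]),
                    se=float(rec[dialect["se"]]),
                    p=float(rec[dialect["p"]]),
                    n=(float(rec[n_col]) if n_col in rec and pd.notna(rec[n_col]) else None),
                    eaf=(float(rec[eaf_col]) if eaf_col in rec and pd.notna(rec[eaf_col]) else None),
                )
            )
        except (ValueError, TypeError) as exc:
            msg = f"{path} line {i}: {exc}"
            if on_error == "skip":
                logger.warning("skipping malformed row: %s", msg)
                continue
            raise RowError(msg) from exc
    return GwasStudy(
        trait_label=trait_label or Path(path).stem,
        ancestry_tag=ancestry_tag,
        sex_tag=sex_tag,
        stats=stats,
    )


def write_sumstats(study: GwasStudy, path) -> None:
    rows = [
        {
            "chrom": s.key.chrom,
            "pos": s.key.pos,
            "allele1": s.key.allele1,
            "allele2": s.key.allele2,
            "rsid": s.key.rsid if s.key.rsid is not None else "",
            "effect_allele": s.effect_allele,
            "beta": repr(s.beta),
            "se": repr(s.se),
            "p": repr(s.p),
            "n": "" if s.n is None else repr(s.n),
            "eaf": "" if s.eaf is None else repr(s.eaf),
        }
        for s in study.stats
    ]
    pd.DataFrame(rows, columns=list(DEFAULT_SUMSTAT_DIALECT)).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def read_intervals(path, cell_type: str | None = None) -> AnnotationSet:
    """Read a 3-column BED-like file (0-based half-open) into an AnnotationSet."""
    ann = AnnotationSet(cell_type or Path(path).stem)
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise RowError(f"{path} line {i}: expected >=3 fields")
            try:
                ann.add(parts[0], int(parts[1]), int(parts[2]))
            except (ValueError, RowError) as exc:
                raise RowError(f"{path} line {i}: {exc}") from exc
    return ann


def write_intervals(ann: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end in ann.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# dosages
# ---------------------------------------------------------------------------

@dataclass
class DosageFragment:
    """Dosages for requested variants plus the missing-variant report."""

    dosages: pd.DataFrame
    counted_alleles: dict[str, str]
    missing: list[VariantKey]


def read_dosages(path, variants: Sequence[VariantKey], fmt: str = "table") -> DosageFragment:
    """Read a dosage matrix for the requested variants.

    ``table`` format: first column ``iid``; remaining columns named
    ``chrom:pos:allele1:allele2:counted_allele``. Dosage counts the stated
    counted allele; any flip to the risk allele happens downstream. ``vcf``
    accepts an uncompressed VCF-dialect file with a DS FORMAT field or hard
    GT calls.
    """
    if fmt == "vcf":
        return _read_dosages_vcf(path, variants)
    df = _read_table(path).set_index("iid")
    col_by_key: dict[VariantKey, tuple[str, str]] = {}
    for col in df.columns:
        parts = col.split(":")
        if len(parts) != 5:
            raise FormatError(f"{path}: dosage column {col!r} is not chrom:pos:a1:a2:counted")
        key = VariantKey(parts[0], int(parts[1]), parts[2], parts[3])
        col_by_key[key] = (col, parts[4].upper())
    data, counted, missing = {}, {}, []
    for v in variants:
        if v not in col_by_key:
            missing.append(v)
            continue
        col, allele = col_by_key[v]
        vals = pd.to_numeric(df[col], errors="coerce").astype(float)
        if ((vals < 0) | (vals > 2)).any():
            raise RowError(f"{path}: dosage out of [0,2] in column {col}")
        data[v.vid] = vals
        counted[v.vid] = allele
    if missing:
        logger.warning("%d requested variant(s) absent from %s", len(missing), path)
    out = pd.DataFrame(data, index=df.index)
    return DosageFragment(out, counted, missing)


def _read_dosages_vcf(path, variants: Sequence[VariantKey]) -> DosageFragment:
    import pysam

    wanted = {v: v for v in variants}
    vf = pysam.VariantFile(str(path))
    ids = list(vf.header.samples)
    data, counted, found = {}, {}, set()
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            continue
        try:
            key = VariantKey(str(rec.chrom), rec.pos, rec.ref, rec.alts[0])
        except ValueError:
            continue
        if key not in wanted:
            continue
        found.add(wanted[key])
        vals = []
        for sample in rec.samples.values():
            if "DS" in sample and sample["DS"] is not None:
                vals.append(float(sample["DS"]))
            else:
                gt = sample.get("GT")
                vals.append(np.nan if gt is None or None in gt else float(sum(gt)))
        data[key.vid] = vals
        counted[key.vid] = rec.alts[0].upper()  # DS counts the ALT allele
    missing = [v for v in variants if v not in found]
    return DosageFragment(pd.DataFrame(data, index=ids), counted, missing)


def write_dosages(frag: DosageFragment, variants: Mapping[str, VariantKey], path) -> None:
    df = frag.dosages.copy()
    df.columns = [
        f"{variants[c].chrom}:{variants[c].pos}:{variants[c].allele1}:"
        f"{variants[c].allele2}:{frag.counted_alleles[c]}"
        for c in df.columns
    ]
    df.index.name = "iid"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# LD panels
# ---------------------------------------------------------------------------

def write_ld_panel(panel: LdPanel, prefix) -> None:
    with open(f"{prefix}.maf.tsv", "w") as fh:
        fh.write("chrom\tpos\tallele1\tallele2\tmaf\n")
        for v in sorted(panel._maf, key=lambda v: (v.chrom, v.pos, v.alleles)):
            fh.write(f"{v.chrom}\t{v.pos}\t{v.allele1}\t{v.allele2}\t{panel._maf[v]!r}\n")
    with open(f"{prefix}.r2.tsv", "w") as fh:
        fh.write("vid_a\tvid_b\tr2\n")
        for a, b, value in sorted(panel.pairs(), key=lambda t: (t[0].vid, t[1].vid)):
            fh.write(f"{a.vid}\t{b.vid}\t{value!r}\n")


def read_ld_panel(prefix, population_tag: str | None = None) -> LdPanel:
    prefix = Path(prefix)
    panel = LdPanel(population_tag or prefix.name)
    maf = pd.read_csv(f"{prefix}.maf.tsv", sep="\t", dtype=str)
    keys = {}
    for row in maf.itertuples(index=False):
        v = VariantKey(str(row.chrom), int(row.pos), row.allele1, row.allele2)
        keys[v.vid] = v
        panel.set_maf(v, float(row.maf))
    r2 = pd.read_csv(f"{prefix}.r2.tsv", sep="\t", dtype=str)
    for row in r2.itertuples(index=False):
        panel.set_r2(keys[row.vid_a], keys[row.vid_b], float(row.r2))
    return panel


# ---------------------------------------------------------------------------
# cohorts and config
# ---------------------------------------------------------------------------

def write_cohort(cohort: CohortTable, prefix) -> None:
    prefix = Path(prefix)
    samples = cohort.samples.copy()
    samples.index.name = "iid"
    samples.to_csv(f"{prefix}.samples.tsv", sep="\t")
    frag = DosageFragment(cohort.dosages, cohort.counted_alleles, [])
    write_dosages(frag, cohort.variants, f"{prefix}.dosages.tsv")


def read_cohort(prefix) -> CohortTable:
    prefix = Path(prefix)
    samples = pd.read_csv(f"{prefix}.samples.tsv", sep="\t", index_col="iid")
    for col in samples.columns:
        if col in ("sex", "ancestry_label"):
            continue
        converted = pd.to_numeric(samples[col], errors="coerce")
        if converted.notna().sum() >= samples[col].notna().sum():
            samples[col] = converted
    dos = pd.read_csv(f"{prefix}.dosages.tsv", sep="\t", index_col="iid")
    variants, counted, data = {}, {}, {}
    for col in dos.columns:
        chrom, pos, a1, a2, ca = col.split(":")
        key = VariantKey(chrom, int(pos), a1, a2)
        variants[key.vid] = key
        counted[key.vid] = ca
        data[key.vid] = dos[col].astype(float)
    return CohortTable(samples, pd.DataFrame(data, index=dos.index), counted, variants)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
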