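"""Genomic feature annotation for DMR candidate windows.

Epimutation candidates (differential DNA methylation regions, DMRs) are
characterised here by five feature subgroups — CpG information, repeat
elements, transcription-factor consensus motifs, short DNA sequence motifs
and mammalian position-weight-matrix motifs — evaluated on a base window
and on 1 kb / 5 kb / 100 kb flanks upstream and downstream of it.  A
:class:`FeatureCatalog` fixes the ordered schema; :func:`extract_features`
turns one genomic window into a fixed-length numeric vector under it.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "REGIONS",
    "SUBGROUPS",
    "GenomeSequence",
    "GenomicWindow",
    "RepeatAnnotation",
    "FeatureSpec",
    "FeatureCatalog",
    "default_catalog",
    "count_cpg",
    "cpg_density",
    "count_motif_hits",
    "count_pwm_hits",
    "count_repeat_overlaps",
    "extract_features",
    "extract_feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
    "reverse_complement",
    "pwm_log_odds",
]

# ---------------------------------------------------------------------------
# schema constants

#: flank regions relative to the base window, in catalog order
REGIONS = ("base", "up1k", "dn1k", "up5k", "dn5k", "up100k", "dn100k")

#: feature subgroups with their default sizes (CpG information, repeat
#: elements, transcription factors, sequence motifs, mammalian motifs)
SUBGROUPS = (
    "cpg_info",
    "repeat_element",
    "transcription_factor",
    "sequence_motif",
    "mammalian_motif",
)

DEFAULT_SUBGROUP_SIZES = {
    "cpg_info": 3,
    "repeat_element": 216,
    "transcription_factor": 207,
    "sequence_motif": 60,
    "mammalian_motif": 348,
}

_FLANK_BP = {"up1k": 1_000, "dn1k": 1_000, "up5k": 5_000, "dn5k": 5_000,
             "up100k": 100_000, "dn100k": 100_000}

IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

_BASES = "ACGT"
# byte → base index; N and anything unexpected → 4
_ENC = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def reverse_complement(pattern: str) -> str:
    """Reverse complement of an IUPAC string (case preserved as upper)."""
    return pattern.upper().translate(_COMPLEMENT)[::-1]


def _encode(sequence: str) -> np.ndarray:
    return _ENC[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# containers


class GenomeSequence:
    """Per-chromosome DNA sequence with length bookkeeping.

    Sequences are stored upper-case; lookups outside ``[0, length)`` raise.
    """

    def __init__(self, chromosomes: Mapping[str, str]):
        if len(set(chromosomes)) != len(chromosomes):
            raise ValueError("duplicate chromosome names")
        self._seq = {name: seq.upper() for name, seq in chromosomes.items()}
        self.lengths = {name: len(seq) for name, seq in self._seq.items()}

    @property
    def names(self) -> list[str]:
        return list(self._seq)

    @classmethod
    def from_fasta(cls, path) -> "GenomeSequence":
        from pyfaidx import Fasta

        with Fasta(str(path), rebuild=True) as fa:
            return cls({name: str(fa[name][:]) for name in fa.keys()})

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seq.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def sequence(self, chrom: str, start: int, end: int) -> str:
        length = self.lengths[chrom]
        if not (0 <= start < end <= length):
            raise ValueError(
                f"window {chrom}:{start}-{end} outside [0, {length})")
        return self._seq[chrom][start:end]

    def flank_sequence(self, window: "GenomicWindow", region: str) -> str:
        """Sequence of a flank region, clipped at chromosome bounds.

        Returns "" when the flank is fully clipped away.
        """
        if region == "base":
            return self.sequence(window.chrom, window.start, window.end)
        k = _FLANK_BP[region]
        length = self.lengths[window.chrom]
        if region.startswith("up"):
            lo, hi = max(0, window.start - k), window.start
        else:
            lo, hi = window.end, min(length, window.end + k)
        return self._seq[window.chrom][lo:hi]


@dataclass(frozen=True, order=True)
class GenomicWindow:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class RepeatAnnotation:
    """Interval collection of repeat elements keyed by family name."""

    def __init__(self):
        self._trees: dict[str, IntervalTree] = {}
        self.families: set[str] = set()
        self._records: list[tuple[str, int, int, str]] = []

    def add(self, chrom: str, start: int, end: int, family: str) -> None:
        if not 0 <= start < end:
            raise ValueError(f"invalid repeat interval {start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, family)
        self.families.add(family)
        self._records.append((chrom, start, end, family))

    def __len__(self) -> int:
        return len(self._records)

    def records(self) -> list[tuple[str, int, int, str]]:
        return list(self._records)

    def count_overlaps(self, chrom: str, start: int, end: int,
                       family: str) -> int:
        tree = self._trees.get(chrom)
        if tree is None or start >= end:
            return 0
        return sum(1 for iv in tree.overlap(start, end) if iv.data == family)

    # -- RepeatMasker ".out" dialect ------------------------------------
    # whitespace-delimited, 3 header lines; columns used: 5 query name,
    # 6 begin, 7 end (1-based inclusive), 10 repeat name, 11 class/family.

    @classmethod
    def from_repeatmasker(cls, path) -> "RepeatAnnotation":
        ann = cls()
        with open(path) as fh:
            for lineno, line in enumerate(fh):
                if lineno < 3 or not line.strip():
                    continue
                parts = line.split()
                chrom = parts[4]
                begin, end = int(parts[5]), int(parts[6])
                family = parts[9]
                ann.add(chrom, begin - 1, end, family)
        return ann

    def to_repeatmasker(self, path) -> None:
        header = (
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat\n"
            "score  div. del. ins.  sequence  begin  end   (left)  repeat"
            "    class/family\n"
            "\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            for chrom, start, end, family in self._records:
                fh.write(
                    f"  225  10.0  0.0  0.0  {chrom}  {start + 1}  {end}"
                    f"  (0)  +  {family}  {family}  1  {end - start}  (0)"
                    f"  1\n"
                )


# ---------------------------------------------------------------------------
# catalog


@dataclass(frozen=True)
class FeatureSpec:
    """One feature: a pattern evaluated on one region of a window.

    ``pattern`` holds an IUPAC consensus (motif subgroups), a repeat family
    name (repeat_element), a PWM identifier (mammalian_motif) or a statistic
    tag in {length, cpg_count, cpg_density} (cpg_info).
    """

    name: str
    subgroup: str
    region: str
    pattern: str

    def __post_init__(self):
        if self.subgroup not in SUBGROUPS:
            raise ValueError(f"unknown subgroup {self.subgroup!r}")
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")


class FeatureCatalog:
    """Ordered feature schema plus the PWM definitions it references."""

    def __init__(self, specs: Sequence[FeatureSpec],
                 pwms: Mapping[str, np.ndarray] | None = None):
        keys = [(s.subgroup, s.name, s.region) for s in specs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subgroup, name, region) in catalog")
        self.specs = list(specs)
        self.pwms = {k: np.asarray(v, dtype=float) for k, v in
                     (pwms or {}).items()}
        for spec in self.specs:
            if spec.subgroup == "mammalian_motif" and spec.pattern not in self.pwms:
                raise ValueError(f"PWM {spec.pattern!r} not defined")

    def __len__(self) -> int:
        return len(self.specs)

    def __iter__(self):
        return iter(self.specs)

    @property
    def names(self) -> list[str]:
        return [f"{s.name}:{s.region}" for s in self.specs]

    @property
    def subgroup_sizes(self) -> dict[str, int]:
        sizes = {g: 0 for g in SUBGROUPS}
        for s in self.specs:
            sizes[s.subgroup] += 1
        return sizes

    def subset(self, indices: Sequence[int]) -> "FeatureCatalog":
        specs = [self.specs[i] for i in indices]
        pwms = {s.pattern: self.pwms[s.pattern] for s in specs
                if s.subgroup == "mammalian_motif"}
        return FeatureCatalog(specs, pwms)

    # -- columnar text serialization ------------------------------------

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tsubgroup\tregion\tpattern\tpwm\n")
            for s in self.specs:
                pwm = ""
                if s.subgroup == "mammalian_motif":
                    m = self.pwms[s.pattern]
                    pwm = ";".join(",".join(f"{v:.6g}" for v in row)
                                   for row in m)
                fh.write(f"{s.name}\t{s.subgroup}\t{s.region}\t"
                         f"{s.pattern}\t{pwm}\n")

    @classmethod
    def from_tsv(cls, path) -> "FeatureCatalog":
        specs, pwms = [], {}
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("name\t"):
                raise ValueError("not a catalog file")
            for line in fh:
                name, subgroup, region, pattern, pwm = (
                    line.rstrip("\n").split("\t"))
                specs.append(FeatureSpec(name, subgroup, region, pattern))
                if pwm:
                    pwms[pattern] = np.array(
                        [[float(v) for v in row.split(",")]
                         for row in pwm.split(";")])
        return cls(specs, pwms)


def _cycle_regions(n: int) -> list[str]:
    return [REGIONS[i % len(REGIONS)] for i in range(n)]


def default_catalog(subgroup_sizes: Mapping[str, int] | None = None,
                    seed: int = 0) -> FeatureCatalog:
    """Build the full annotation schema with the standard subgroup sizes.

    CpG information (3), repeat elements (216), transcription factors (207),
    sequence motifs (60) and mammalian PWM motifs (348) — 834 features in
    total by default.  Only a handful of motifs are fixed by the DMR
    literature (CCGG, GCGC, TCGG); the remaining entries are reproducible
    placeholder patterns, since any concrete repeat-family / TF / PWM list
    is a configuration choice of the annotation run.  Patterns are drawn
    deterministically from ``seed`` and spread over the base window and the
    six flank regions.
    """
    sizes = dict(DEFAULT_SUBGROUP_SIZES)
    if subgroup_sizes:
        sizes.update(subgroup_sizes)
    rng = np.random.default_rng(seed)
    specs: list[FeatureSpec] = []
    pwms: dict[str, np.ndarray] = {}

    for tag in ("length", "cpg_count", "cpg_density")[: sizes["cpg_info"]]:
        specs.append(FeatureSpec(f"cpg_{tag}" if not tag.startswith("cpg")
                                 else tag, "cpg_info", "base", tag))

    n = sizes["repeat_element"]
    n_fam = -(-n // len(REGIONS))
    families = [f"repfam{j:03d}" for j in range(n_fam)]
    pairs = [(fam, reg) for fam in families for reg in REGIONS][:n]
    for fam, reg in pairs:
        specs.append(FeatureSpec(fam, "repeat_element", reg, fam))

    n = sizes["transcription_factor"]
    regions = _cycle_regions(n)
    for j in range(n):
        length = int(rng.integers(6, 13))
        # consensus with a few degenerate IUPAC positions
        consensus = "".join(
            rng.choice(list("RYSWKM")) if rng.random() < 0.2
            else rng.choice(list(_BASES))
            for _ in range(length))
        specs.append(FeatureSpec(f"tf{j:03d}", "transcription_factor",
                                 regions[j], consensus))

    n = sizes["sequence_motif"]
    fixed = [("motif_CCGG", "CCGG"), ("motif_GCGC", "GCGC"),
             ("motif_TCGG", "TCGG")][: n]
    regions = _cycle_regions(n)
    for j, (name, pat) in enumerate(fixed):
        specs.append(FeatureSpec(name, "sequence_motif", "base", pat))
    for j in range(len(fixed), n):
        length = int(rng.integers(4, 9))
        pat = "".join(rng.choice(list(_BASES)) for _ in range(length))
        specs.append(FeatureSpec(f"motif{j:03d}", "sequence_motif",
                                 regions[j], pat))

    n = sizes["mammalian_motif"]
    regions = _cycle_regions(n)
    for j in range(n):
        length = int(rng.integers(6, 11))
        mat = rng.dirichlet([0.5] * 4, size=length).T  # 4 x L, peaked columns
        name = f"pwm{j:03d}"
        pwms[name] = mat
        specs.append(FeatureSpec(name, "mammalian_motif", regions[j], name))

    return FeatureCatalog(specs, pwms)


# ---------------------------------------------------------------------------
# primitive counters


def count_cpg(sequence: str) -> int:
    """Number of CpG dinucleotides (positions i with seq[i:i+2] == "CG").

    CG cannot overlap itself, so the non-overlapping count is exact.
    N (or any non-ACGT character) never participates in a match.
    """
    return sequence.upper().count("CG")


def cpg_density(sequence: str) -> float:
    """CpG sites per 100 bases; raises on an empty (degenerate) window."""
    if len(sequence) == 0:
        raise ValueError("cpg_density of empty sequence is undefined")
    return 100.0 * count_cpg(sequence) / len(sequence)


def _iupac_regex(pattern: str) -> str:
    parts = []
    for ch in pattern.upper():
        if ch not in IUPAC_CODES:
            raise ValueError(f"invalid IUPAC symbol {ch!r} in {pattern!r}")
        opts = IUPAC_CODES[ch]
        parts.append(opts if len(opts) == 1 else f"[{opts}]")
    return "".join(parts)


def count_motif_hits(sequence: str, iupac_pattern: str,
                     scan_both_strands: bool = True) -> int:
    """Count (possibly overlapping) IUPAC consensus matches.

    Both-strand scanning adds matches of the reverse-complement pattern on
    the forward sequence; a palindromic (self-reverse-complement) pattern is
    counted once per site, not twice.
    """
    if not iupac_pattern:
        raise ValueError("empty pattern")
    fwd = _iupac_regex(iupac_pattern)
    seq = sequence.upper()
    # lookahead makes overlapping occurrences countable
    count = len(re.findall(f"(?={fwd})", seq))
    if scan_both_strands:
        rc = reverse_complement(iupac_pattern)
        if rc != iupac_pattern.upper():
            count += len(re.findall(f"(?={_iupac_regex(rc)})", seq))
    return count


def pwm_log_odds(pwm: np.ndarray, pseudocount: float = 0.01) -> np.ndarray:
    """Column-normalised log-odds matrix vs a uniform background."""
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[0] != 4 or np.any(pwm < 0):
        raise ValueError("PWM must be a non-negative 4 x L matrix")
    probs = (pwm + pseudocount) / (pwm + pseudocount).sum(axis=0)
    return np.log(probs / 0.25)


def _pwm_reverse_complement(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]  # swap A<->T, C<->G and reverse positions


def _pwm_scan_count(encoded: np.ndarray, lo: np.ndarray,
                    threshold: float) -> int:
    L = lo.shape[1]
    n = encoded.size - L + 1
    if n <= 0:
        return 0
    # N positions score -inf so gap bases can never contribute a hit
    lo5 = np.vstack([lo, np.full((1, L), -np.inf)])
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    scores = lo5[windows, np.arange(L)].sum(axis=1)
    return int(np.count_nonzero(scores >= threshold - 1e-12))


def count_pwm_hits(sequence: str, pwm: np.ndarray,
                   score_threshold_fraction: float = 0.8,
                   scan_both_strands: bool = True,
                   pseudocount: float = 0.01) -> int:
    """Count PWM hits above a fraction of the attainable score range.

    The log-odds score (uniform background, additive pseudocount) at every
    offset is compared with ``min + fraction * (max - min)`` where min/max
    are the lowest/highest scores any sequence could reach.  Both strands
    are scanned unless the PWM is its own reverse complement.
    """
    if not 0 < score_threshold_fraction <= 1:
        raise ValueError("threshold fraction must be in (0, 1]")
    lo = pwm_log_odds(pwm, pseudocount)
    smin, smax = lo.min(axis=0).sum(), lo.max(axis=0).sum()
    threshold = smin + score_threshold_fraction * (smax - smin)
    encoded = _encode(sequence)
    count = _pwm_scan_count(encoded, lo, threshold)
    if scan_both_strands:
        rc = _pwm_reverse_complement(np.asarray(pwm, dtype=float))
        if not np.allclose(rc, pwm):
            count += _pwm_scan_count(encoded, pwm_log_odds(rc, pseudocount),
                                     threshold)
    return count


def count_repeat_overlaps(window: GenomicWindow,
                          annotation: RepeatAnnotation, family: str) -> int:
    """Number of annotated intervals of ``family`` overlapping by >= 1 bp."""
    return annotation.count_overlaps(window.chrom, window.start, window.end,
                                     family)


# ---------------------------------------------------------------------------
# vector extraction


def _flank_window(window: GenomicWindow, region: str,
                  chrom_length: int) -> tuple[int, int]:
    if region == "base":
        return window.start, window.end
    k = _FLANK_BP[region]
    if region.startswith("up"):
        return max(0, window.start - k), window.start
    return window.end, min(chrom_length, window.end + k)


def extract_features(window: GenomicWindow, genome: GenomeSequence,
                     repeats: RepeatAnnotation,
                     catalog: FeatureCatalog) -> np.ndarray:
    """Annotate one window under a catalog; returns a vector of len(catalog).

    Flank regions are clipped at chromosome ends; a fully clipped flank
    contributes 0 for every count and 0 for density (degenerate-window
    rule), keeping the vector length fixed.
    """
    length = genome.lengths.get(window.chrom)
    if length is None or not (0 <= window.start < window.end <= length):
        raise ValueError(f"window {window} outside genome")

    region_seq: dict[str, str] = {}
    values = np.empty(len(catalog), dtype=float)
    for idx, spec in enumerate(catalog):
        if spec.subgroup == "cpg_info":
            base = genome.sequence(window.chrom, window.start, window.end)
            if spec.pattern == "length":
                values[idx] = len(window)
            elif spec.pattern == "cpg_count":
                values[idx] = count_cpg(base)
            else:  # cpg_density
                values[idx] = cpg_density(base) if base else 0.0
            continue
        if spec.subgroup == "repeat_element":
            lo, hi = _flank_window(window, spec.region, length)
            values[idx] = (repeats.count_overlaps(window.chrom, lo, hi,
                                                  spec.pattern)
                           if lo < hi else 0)
            continue
        seq = region_seq.get(spec.region)
        if seq is None:
            seq = genome.flank_sequence(window, spec.region)
            region_seq[spec.region] = seq
        if not seq:
            values[idx] = 0.0
        elif spec.subgroup == "mammalian_motif":
            values[idx] = count_pwm_hits(seq, catalog.pwms[spec.pattern])
        else:
            values[idx] = count_motif_hits(seq, spec.pattern)
    return values


def extract_feature_matrix(windows: Iterable[GenomicWindow],
                           genome: GenomeSequence,
                           repeats: RepeatAnnotation,
                           catalog: FeatureCatalog) -> pd.DataFrame:
    """Feature vectors for many windows as a DataFrame in catalog order."""
    windows = list(windows)
    data = np.array([extract_features(w, genome, repeats, catalog)
                     for w in windows]).reshape(len(windows), len(catalog))
    index = [f"{w.chrom}:{w.start}-{w.end}" for w in windows]
    return pd.DataFrame(data, index=index, columns=catalog.names)


def write_feature_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="window")


def read_feature_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="window")
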