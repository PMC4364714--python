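"""Synthetic-data generators for every input the pipeline consumes.

The generators emulate the study's raw materials with recorded ground truth:

* a host chromosome carrying a homozygous transgene concatemer flanked by a
  target-site duplication, and 100 bp paired-end reads from 300-500 bp
  library inserts at ~30x coverage;
* cohorts of animals with sex-specific ganglionic-zone fractions and a hard
  obstruction threshold that determines megacolon status;
* time-stamped 2-D tracks of migrating enteric neural crest cells;
* negative-binomial RNA-seq count matrices with chromosome annotation.

Coordinates are 0-based half-open internally and converted to 1-based only
when standard formats (SAM) are written.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ReferenceGenome",
    "TransgeneUnit",
    "InsertionTruth",
    "ReadSimulation",
    "Cohort",
    "Track",
    "CountMatrix",
    "make_reference",
    "build_insertion_allele",
    "simulate_paired_reads",
    "simulate_cohort",
    "simulate_tracks",
    "simulate_counts",
    "default_transgene_units",
    "write_fasta",
    "write_fastq",
    "write_sam",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")

# Sex-specific ganglionic-fraction means (% of colon length) by age group,
# and the obstruction threshold beneath which megacolon occurs systematically.
COHORT_DEFAULTS = {
    "weaning": {"mu_male": 79.0, "mu_female": 89.0},
    "neonate": {"mu_male": 74.0, "mu_female": 90.0},
}
DEFAULT_SIGMA = 5.0
DEFAULT_THRESHOLD = 80.0

# Control-condition migration speed of leading eNCC (micron/min).
DEFAULT_SPEED = 0.58


@dataclass(frozen=True)
class ReferenceGenome:
    """A synthetic host chromosome (stand-in for a mouse autosome)."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class TransgeneUnit:
    """One transgene repeat unit of the co-injected concatemer."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class InsertionTruth:
    """Ground-truth architecture of a simulated transgene insertion.

    ``array_segments`` lists (unit name, array start, array end) for every
    repeat copy, in array coordinates (0-based, relative to the first base
    of the concatemer).
    """

    host_site: int
    dup_length: int
    unit_copies: dict[str, int]
    array_length: int
    zygosity: str
    array_segments: tuple[tuple[str, int, int], ...] = field(default=())

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["array_segments"] = [list(s) for s in self.array_segments]
        return json.dumps(d, indent=1)

    @property
    def left_junction(self) -> int:
        """Host coordinate of the host->array junction (end of the first
        duplication copy)."""
        return self.host_site + self.dup_length

    @property
    def right_junction(self) -> int:
        """Host coordinate of the array->host junction (start of the second
        duplication copy, i.e. the duplication start)."""
        return self.host_site


@dataclass(frozen=True)
class InsertionAllele:
    """A mutant allele sequence plus the truth record describing it."""

    sequence: str
    truth: InsertionTruth
    host_name: str
    unit_names: tuple[str, ...]


def _random_dna(n: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode("ascii")


def make_reference(
    length: int, gc_fraction: float = 0.42, seed: int = 0, name: str = "host"
) -> ReferenceGenome:
    """Generate a random host chromosome of ``length`` bases.

    Reproducible given (length, gc_fraction, seed); the realised GC content
    converges on ``gc_fraction`` for long sequences.
    """
    if length < 1:
        raise ValueError(f"reference length must be positive, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return ReferenceGenome(name=name, sequence=_random_dna(length, gc_fraction, rng))


def make_transgene_unit(
    name: str, length: int, seed: int = 0, gc_fraction: float = 0.5
) -> TransgeneUnit:
    if length < 1000:
        raise ValueError("transgene units are >= 1 kb")
    rng = np.random.default_rng(seed)
    return TransgeneUnit(name=name, sequence=_random_dna(length, gc_fraction, rng))


def default_transgene_units(
    unit_length: int = 7000, seed: int = 0
) -> tuple[TransgeneUnit, TransgeneUnit]:
    """The two co-injected transgenes: a pigmentation minigene and a
    NCC-marking fluorescent reporter.

    Unit lengths default to 7 kb each so that a 50+50-copy alternating
    concatemer totals 700 kb per allele.
    """
    return (
        make_transgene_unit("Tyr-minigene", unit_length, seed=seed + 11),
        make_transgene_unit("SRYp-YFP", unit_length, seed=seed + 13),
    )


def build_insertion_allele(
    ref: ReferenceGenome,
    site: int,
    units: Sequence[TransgeneUnit],
    copies: Sequence[int],
    dup_length: int,
    zygosity: str = "hom",
) -> InsertionAllele:
    """Insert an interleaved transgene concatemer flanked by a target-site
    duplication into ``ref`` at ``site``.

    The ``dup_length`` host bases immediately downstream of ``site`` end up
    present twice, one copy on each side of the array, so the mutant allele
    is ``ref.length + dup_length + array_length`` bases long.  Units are
    interleaved round-robin (equimolar co-injection) until every unit's copy
    count is exhausted.
    """
    if len(units) != len(copies):
        raise ValueError("units and copies must have equal length")
    if any(c < 0 for c in copies):
        raise ValueError("copy counts must be non-negative")
    if sum(copies) == 0:
        raise ValueError("at least one transgene copy is required")
    if site < 0 or site + dup_length > ref.length:
        raise ValueError(
            f"site {site} + dup_length {dup_length} out of range for "
            f"reference of length {ref.length}"
        )
    names = [u.name for u in units]
    if len(set(names)) != len(names):
        raise ValueError("transgene unit names must be unique")

    # Round-robin interleave: u1 u2 u1 u2 ... until copies run out.
    order: list[int] = []
    remaining = list(copies)
    while any(r > 0 for r in remaining):
        for i, r in enumerate(remaining):
            if r > 0:
                order.append(i)
                remaining[i] -= 1

    segments: list[tuple[str, int, int]] = []
    pos = 0
    parts: list[str] = []
    for i in order:
        u = units[i]
        segments.append((u.name, pos, pos + u.length))
        parts.append(u.sequence)
        pos += u.length
    array_seq = "".join(parts)
    array_length = pos

    dup = ref.sequence[site : site + dup_length]
    mutant = ref.sequence[:site] + dup + array_seq + dup + ref.sequence[site + dup_length :]

    truth = InsertionTruth(
        host_site=site,
        dup_length=dup_length,
        unit_copies={u.name: int(c) for u, c in zip(units, copies) if c > 0},
        array_length=array_length,
        zygosity=zygosity,
        array_segments=tuple(segments),
    )
    return InsertionAllele(
        sequence=mutant,
        truth=truth,
        host_name=ref.name,
        unit_names=tuple(u.name for u in units if dict(truth.unit_copies).get(u.name)),
    )


# ---------------------------------------------------------------------------
# Paired-end read simulation
# ---------------------------------------------------------------------------

ALIGNMENT_COLUMNS = [
    "read",
    "mate_index",
    "contig",
    "pos",
    "strand",
    "mapped",
    "mate_contig",
    "mate_pos",
    "mate_mapped",
    "insert_size",
    "proper",
]


@dataclass
class ReadSimulation:
    """Output of :func:`simulate_paired_reads`.

    ``alignments`` holds one row per read (two per fragment) with truth
    mapping onto the host chromosome and transgene unit contigs; fragments
    straddling a host/transgene junction yield non-proper pairs.
    ``fragments`` is the truth fragment list (allele index, start, length in
    allele coordinates).
    """

    alignments: pd.DataFrame
    fragments: pd.DataFrame
    contig_lengths: dict[str, int]
    read_len: int
    insert_mean: float
    insert_sd: float
    alleles: tuple = ()

    def junction_spanning_fragments(
        self, truth: InsertionTruth, margin: int = 0
    ) -> np.ndarray:
        """Boolean mask of truth fragments that overlap a host/array junction
        of an insertion allele.

        With ``margin=0`` any overlap counts (every such fragment yields a
        non-proper pair).  With ``margin=read_len`` only fragments whose
        junction falls at least one read length inside both ends count: these
        are the fragments whose two reads map cleanly to opposite sides and
        so appear as host/transgene chimeric pairs.
        """
        left = truth.left_junction
        right = left + truth.array_length
        s = self.fragments["start"].to_numpy()
        e = s + self.fragments["length"].to_numpy()
        ins = self.fragments["allele_has_insertion"].to_numpy()
        if margin:
            hit = lambda j: (s + margin <= j) & (e - margin >= j)
        else:
            hit = lambda j: (s < j) & (e > j)
        return ins & (hit(left) | hit(right))


def _allele_blocks(allele) -> tuple[np.ndarray, list[tuple[str, int]], int, bool]:
    """Decompose an allele into truth-mapping blocks.

    Returns (block start offsets in allele coords, [(contig, contig start)]
    per block, allele length, has_insertion).
    """
    if isinstance(allele, ReferenceGenome):
        return np.array([0]), [(allele.name, 0)], allele.length, False
    if isinstance(allele, InsertionAllele):
        t = allele.truth
        L = len(allele.sequence)
        starts = [0]
        contigs: list[tuple[str, int]] = [(allele.host_name, 0)]
        base = t.host_site + t.dup_length  # array begins here in allele coords
        for name, s, e in t.array_segments:
            starts.append(base + s)
            contigs.append((name, 0))
        # second duplication copy + downstream host
        starts.append(base + t.array_length)
        contigs.append((allele.host_name, t.host_site))
        return np.asarray(starts), contigs, L, True
    raise TypeError(f"unsupported allele type: {type(allele)!r}")


def simulate_paired_reads(
    alleles: Sequence,
    coverage: float,
    read_len: int = 100,
    insert_mean: float = 400.0,
    insert_sd: float = 35.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> ReadSimulation:
    """Simulate paired-end reads from a set of alleles.

    ``alleles`` mixes :class:`ReferenceGenome` and :class:`InsertionAllele`
    objects; pass the mutant allele twice for a homozygote.  The number of
    pairs is ``coverage * total allele length / (4 * read_len)``, so with a
    two-allele diploid the haploid reference receives ``coverage``-fold
    depth.  Fragment lengths are Gaussian(insert_mean, insert_sd) truncated
    to [2*read_len, 2*insert_mean].

    Truth alignments: a read fully inside one host segment or one transgene
    repeat copy is mapped to that contig; a read spanning a junction is
    emitted unmapped (pair-level evidence only, no soft clips).  Pairs whose
    mates map to different contigs, or not at all, are non-proper.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_mean <= 2 * read_len:
        raise ValueError("insert_mean must exceed 2*read_len")
    rng = np.random.default_rng(seed)

    blocks = [_allele_blocks(a) for a in alleles]
    lengths = np.array([b[2] for b in blocks], dtype=float)
    total = lengths.sum()
    n_pairs = int(round(coverage * total / (4.0 * read_len)))

    allele_idx = rng.choice(len(alleles), size=n_pairs, p=lengths / total)
    lo, hi = 2 * read_len, 2 * insert_mean
    a, b = (lo - insert_mean) / insert_sd, (hi - insert_mean) / insert_sd
    frag_len = np.rint(
        stats.truncnorm.rvs(a, b, loc=insert_mean, scale=insert_sd,
                            size=n_pairs, random_state=rng)
    ).astype(np.int64)
    starts = np.floor(
        rng.random(n_pairs) * (lengths[allele_idx] - frag_len + 1)
    ).astype(np.int64)

    frames = []
    frag_frames = []
    contig_lengths: dict[str, int] = {}
    for ai, (bstarts, bcontigs, L, has_ins) in enumerate(blocks):
        # record contig lengths implied by this allele
        allele_obj = alleles[ai]
        if isinstance(allele_obj, ReferenceGenome):
            contig_lengths[allele_obj.name] = max(
                contig_lengths.get(allele_obj.name, 0), allele_obj.length
            )
        else:
            t = allele_obj.truth
            host_len = len(allele_obj.sequence) - t.dup_length - t.array_length
            contig_lengths[allele_obj.host_name] = max(
                contig_lengths.get(allele_obj.host_name, 0), host_len
            )
            for name, s, e in t.array_segments:
                contig_lengths[name] = max(contig_lengths.get(name, 0), e - s)

        sel = allele_idx == ai
        if not sel.any():
            continue
        s = starts[sel]
        fl = frag_len[sel]
        r1s, r1e = s, s + read_len
        r2s, r2e = s + fl - read_len, s + fl

        bnames = np.array([c for c, _ in bcontigs], dtype=object)
        boffsets = np.array([o for _, o in bcontigs], dtype=np.int64)

        def classify(rs, re_):
            bi = np.searchsorted(bstarts, rs, side="right") - 1
            bj = np.searchsorted(bstarts, re_ - 1, side="right") - 1
            mapped = bi == bj
            contig = bnames[bi].copy()
            pos = (boffsets[bi] + (rs - bstarts[bi])).astype(float)
            contig[~mapped] = None
            pos[~mapped] = np.nan
            return mapped, contig, pos

        m1, c1, p1 = classify(r1s, r1e)
        m2, c2, p2 = classify(r2s, r2e)
        same = m1 & m2 & (c1 == c2)
        isize = np.where(same, p2 + read_len - p1, np.nan)
        with np.errstate(invalid="ignore"):
            proper = same & (isize >= 2 * read_len) & (isize <= 2 * insert_mean + 1)

        ids = np.char.add(f"a{ai}_frag", np.arange(sel.sum()).astype(str))
        frames.append(
            pd.DataFrame(
                {
                    "read": np.concatenate([ids, ids]),
                    "mate_index": np.concatenate(
                        [np.ones(len(ids), np.int8), np.full(len(ids), 2, np.int8)]
                    ),
                    "contig": np.concatenate([c1, c2]),
                    "pos": np.concatenate([p1, p2]),
                    "strand": np.concatenate(
                        [np.full(len(ids), "+"), np.full(len(ids), "-")]
                    ),
                    "mapped": np.concatenate([m1, m2]),
                    "mate_contig": np.concatenate([c2, c1]),
                    "mate_pos": np.concatenate([p2, p1]),
                    "mate_mapped": np.concatenate([m2, m1]),
                    "insert_size": np.concatenate([isize, -isize]),
                    "proper": np.concatenate([proper, proper]),
                }
            )
        )
        frag_frames.append(
            pd.DataFrame(
                {
                    "read": ids,
                    "allele": ai,
                    "start": s,
                    "length": fl,
                    "allele_has_insertion": has_ins,
                }
            )
        )

    alignments = pd.concat(frames, ignore_index=True)
    fragments = pd.concat(frag_frames, ignore_index=True)

    sim = ReadSimulation(
        alignments=alignments,
        fragments=fragments,
        contig_lengths=contig_lengths,
        read_len=read_len,
        insert_mean=insert_mean,
        insert_sd=insert_sd,
        alleles=tuple(alleles),
    )
    sim._error_rate = error_rate  # used when sequences are materialised
    sim._seed = seed
    return sim


def _allele_sequence(allele) -> str:
    return allele.sequence


def read_sequences(sim: ReadSimulation) -> pd.DataFrame:
    """Materialise read sequences (and apply the uniform substitution-error
    model) for FASTQ/SAM output.  Returns the fragments table with ``seq1``
    and ``seq2`` columns (read 2 reverse-complemented, as sequenced)."""
    rng = np.random.default_rng((getattr(sim, "_seed", 0), 0xC0FFEE))
    err = getattr(sim, "_error_rate", 0.0)
    rl = sim.read_len
    seqs = {i: _allele_sequence(a) for i, a in enumerate(sim.alleles)}
    s1, s2 = [], []
    for allele, start, length in zip(
        sim.fragments["allele"], sim.fragments["start"], sim.fragments["length"]
    ):
        frag_seq = seqs[allele][start : start + length]
        r1 = frag_seq[:rl]
        r2 = frag_seq[-rl:][::-1].translate(_COMPLEMENT)
        s1.append(r1)
        s2.append(r2)
    out = sim.fragments.copy()
    out["seq1"] = s1
    out["seq2"] = s2
    if err > 0:
        for col in ("seq1", "seq2"):
            arr = np.frombuffer("".join(out[col]).encode(), dtype=np.uint8).copy()
            hit = np.nonzero(rng.random(arr.size) < err)[0]
            # substitute with a uniformly chosen *different* base
            cur = arr[hit]
            shift = rng.integers(1, 4, size=hit.size)
            lut = np.full(256, 0, np.uint8)
            for i, bss in enumerate(b"ACGT"):
                lut[bss] = i
            arr[hit] = _BASES[(lut[cur] + shift) % 4]
            joined = arr.tobytes().decode()
            out[col] = [joined[i * rl : (i + 1) * rl] for i in range(len(out))]
    return out


# ---------------------------------------------------------------------------
# Standard-format writers
# ---------------------------------------------------------------------------


def write_fasta(records: Mapping[str, str] | Sequence, path: str | Path) -> None:
    """Write named sequences to FASTA (accepts a mapping or a sequence of
    ReferenceGenome / TransgeneUnit objects)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    if isinstance(records, Mapping):
        items = records.items()
    else:
        items = ((r.name, r.sequence) for r in records)
    seqio_write(
        [SeqRecord(Seq(s), id=n, description="") for n, s in items], str(path), "fasta"
    )


def write_fastq(sim: ReadSimulation, path1: str | Path, path2: str | Path) -> None:
    """Write the simulated pairs as two FASTQ files (uniform quality)."""
    table = read_sequences(sim)
    q = "I" * sim.read_len
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for row in table.itertuples():
            f1.write(f"@{row.read}/1\n{row.seq1}\n+\n{q}\n")
            f2.write(f"@{row.read}/2\n{row.seq2}\n+\n{q}\n")


def write_sam(sim: ReadSimulation, path: str | Path) -> None:
    """Write truth alignments as a valid SAM file (1-based on write)."""
    import pysam

    names = list(sim.contig_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": n, "LN": int(sim.contig_lengths[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    table = read_sequences(sim)
    aln = sim.alignments
    rl = sim.read_len
    by_read: dict[str, list] = {}
    for row in aln.itertuples():
        by_read.setdefault(row.read, []).append(row)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for row in table.itertuples():
            mates = sorted(by_read[row.read], key=lambda r: r.mate_index)
            for mate, seq in zip(mates, (row.seq1, row.seq2)):
                a = pysam.AlignedSegment(out.header)
                a.query_name = mate.read
                a.query_sequence = seq
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                flag = 0x1
                flag |= 0x40 if mate.mate_index == 1 else 0x80
                if mate.proper:
                    flag |= 0x2
                if not mate.mapped:
                    flag |= 0x4
                if not mate.mate_mapped:
                    flag |= 0x8
                if mate.strand == "-" and mate.mapped:
                    flag |= 0x10
                if mate.mate_mapped and mate.mate_index == 1:
                    flag |= 0x20  # mate of read1 is reverse by construction
                a.flag = flag
                if mate.mapped:
                    a.reference_id = tid[mate.contig]
                    pos = int(mate.pos)
                    clen = sim.contig_lengths[mate.contig]
                    a.reference_start = min(pos, max(clen - rl, 0))
                    a.cigarstring = f"{rl}M"
                    a.mapping_quality = 60
                if mate.mate_mapped:
                    a.next_reference_id = tid[mate.mate_contig]
                    a.next_reference_start = int(
                        min(mate.mate_pos, max(sim.contig_lengths[mate.mate_contig] - rl, 0))
                    )
                if not np.isnan(mate.insert_size):
                    a.template_length = int(mate.insert_size)
                out.write(a)


# ---------------------------------------------------------------------------
# Cohorts, tracks, counts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """Per-animal phenotype table.

    Columns: id, sex ('M'/'F'), age_group, ganglionic_fraction (% of colon
    length, in [0, 100]) and megacolon (True when the fraction falls below
    the obstruction threshold).
    """

    animals: pd.DataFrame
    threshold: float

    def to_tsv(self, path: str | Path) -> None:
        self.animals.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, threshold: float = DEFAULT_THRESHOLD) -> "Cohort":
        return cls(animals=pd.read_csv(path, sep="\t"), threshold=threshold)


def simulate_cohort(
    n_male: int,
    n_female: int,
    mu_male: float | None = None,
    mu_female: float | None = None,
    sigma: float = DEFAULT_SIGMA,
    threshold: float = DEFAULT_THRESHOLD,
    age_group: str = "weaning",
    seed: int = 0,
) -> Cohort:
    """Simulate a cohort of homozygous animals.

    Ganglionic fractions are drawn Normal(mu_sex, sigma) truncated to
    [0, 100]; megacolon is deterministic: fraction < threshold.  Sex-specific
    default means come from :data:`COHORT_DEFAULTS` for the age group.
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("cohort sizes must be non-negative")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0 < threshold < 100:
        raise ValueError("threshold must lie in (0, 100)")
    defaults = COHORT_DEFAULTS.get(age_group)
    if defaults is None and (mu_male is None or mu_female is None):
        raise ValueError(f"unknown age group {age_group!r} and no means supplied")
    mu_male = defaults["mu_male"] if mu_male is None else mu_male
    mu_female = defaults["mu_female"] if mu_female is None else mu_female

    rng = np.random.default_rng(seed)

    def draw(n: int, mu: float) -> np.ndarray:
        if sigma == 0:
            return np.full(n, float(np.clip(mu, 0, 100)))
        a, b = (0 - mu) / sigma, (100 - mu) / sigma
        return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)

    frac = np.concatenate([draw(n_male, mu_male), draw(n_female, mu_female)])
    sex = np.array(["M"] * n_male + ["F"] * n_female)
    animals = pd.DataFrame(
        {
            "id": [f"{age_group[:1]}{i:04d}" for i in range(n_male + n_female)],
            "sex": sex,
            "age_group": age_group,
            "ganglionic_fraction": frac,
            "megacolon": frac < threshold,
        }
    )
    return Cohort(animals=animals, threshold=threshold)


@dataclass(frozen=True)
class Track:
    """Time-stamped 2-D positions of one migrating cell.

    ``reference_angle`` is the orientation (radians) of the mesentery axis
    against which heading deviations are measured.
    """

    cell: str
    times: np.ndarray
    positions: np.ndarray
    reference_angle: float = 0.0

    def __post_init__(self):
        if len(self.times) != len(self.positions) or len(self.times) < 2:
            raise ValueError("a track needs >= 2 matched time points")


def simulate_tracks(
    n_cells: int,
    duration: float = 180.0,
    dt: float = 5.0,
    speed_mu: float = DEFAULT_SPEED,
    speed_sd: float = 0.1,
    kappa: float = 4.0,
    reference_angle: float = 0.0,
    seed: int = 0,
) -> list[Track]:
    """Simulate eNCC migration tracks.

    Per-step headings are von Mises around ``reference_angle`` with
    concentration ``kappa`` (kappa=0 gives uniform headings); per-step
    displacement magnitudes are |Normal(speed_mu*dt, speed_sd*dt)|.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 2 * dt:
        raise ValueError("duration must cover at least two steps")
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    rng = np.random.default_rng(seed)
    n_steps = int(duration // dt)
    tracks = []
    for c in range(n_cells):
        if kappa == 0:
            headings = rng.uniform(-np.pi, np.pi, n_steps)
        else:
            headings = rng.vonmises(reference_angle, kappa, n_steps)
        steps = np.abs(rng.normal(speed_mu * dt, speed_sd * dt, n_steps))
        disp = np.column_stack([steps * np.cos(headings), steps * np.sin(headings)])
        pos = np.vstack([[0.0, 0.0], np.cumsum(disp, axis=0)])
        times = np.arange(n_steps + 1) * dt
        tracks.append(
            Track(cell=f"cell{c:03d}", times=times, positions=pos,
                  reference_angle=reference_angle)
        )
    return tracks


def tracks_to_frame(tracks: Sequence[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for ti, (x, y) in zip(t.times, t.positions):
            rows.append((t.cell, ti, x, y, t.reference_angle))
    return pd.DataFrame(rows, columns=["cell", "t", "x", "y", "reference_angle"])


def tracks_from_frame(df: pd.DataFrame) -> list[Track]:
    out = []
    for cell, grp in df.groupby("cell", sort=False):
        grp = grp.sort_values("t")
        ref = float(grp["reference_angle"].iloc[0]) if "reference_angle" in grp else 0.0
        out.append(
            Track(
                cell=str(cell),
                times=grp["t"].to_numpy(float),
                positions=grp[["x", "y"]].to_numpy(float),
                reference_angle=ref,
            )
        )
    return out


@dataclass
class CountMatrix:
    """Genes x samples integer counts with annotation and simulation truth."""

    counts: pd.DataFrame  # genes x samples
    annotation: pd.DataFrame  # index gene: chromosome, start, end
    groups: pd.Series  # per-sample group label
    true_fold: pd.Series  # per-gene designed fold (1.0 = null)

    def to_tsv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.counts.to_csv(prefix.with_suffix(".counts.tsv"), sep="\t")
        self.annotation.to_csv(prefix.with_suffix(".genes.tsv"), sep="\t")


def simulate_counts(
    n_genes: int,
    n_reps_per_group: int = 2,
    lib_sizes: Sequence[float] | None = None,
    dispersion: float = 0.05,
    de_spec: Mapping[str, float] | None = None,
    base_mean: float = 200.0,
    base_sigma: float = 1.0,
    chromosomes: Sequence[str] = ("10", "X", "Y", "1", "2"),
    seed: int = 0,
) -> CountMatrix:
    """Simulate a negative-binomial count matrix for a two-group design.

    Counts have mean ``mu`` and variance ``mu + dispersion * mu**2``
    (dispersion=0 is the Poisson limit).  ``de_spec`` maps gene names
    (``gene0000``-style) to true fold changes (mutant/control, > 0; use the
    reciprocal for downregulation).  The default 2+2 design mirrors a
    two-replicate-per-condition RNA-seq experiment.
    """
    if dispersion < 0:
        raise ValueError("dispersion must be non-negative")
    de_spec = dict(de_spec or {})
    if any(f <= 0 for f in de_spec.values()):
        raise ValueError("true folds must be positive; encode downregulation as 1/fold")
    n_samples = 2 * n_reps_per_group
    if lib_sizes is None:
        lib_sizes = np.ones(n_samples)
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    if lib_sizes.shape != (n_samples,) or (lib_sizes <= 0).any():
        raise ValueError("lib_sizes must be positive, one per sample")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    unknown = set(de_spec) - set(genes)
    if unknown:
        raise ValueError(f"de_spec names unknown genes: {sorted(unknown)[:3]}")

    # Log-normal spread of baseline expression around base_mean
    # (base_sigma=0 pins every gene's mean at base_mean).
    base = base_mean * rng.lognormal(0.0, base_sigma, n_genes)
    fold = np.array([de_spec.get(g, 1.0) for g in genes])
    groups = pd.Series(
        ["control"] * n_reps_per_group + ["mutant"] * n_reps_per_group,
        index=[f"ctrl{i}" for i in range(n_reps_per_group)]
        + [f"mut{i}" for i in range(n_reps_per_group)],
        name="group",
    )
    mu = np.outer(base, lib_sizes)
    mu[:, n_reps_per_group:] *= fold[:, None]
    if dispersion == 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mu * dispersion)
        counts = rng.poisson(lam)
    counts = pd.DataFrame(counts, index=genes, columns=groups.index)

    chrom = rng.choice(list(chromosomes), size=n_genes)
    start = rng.integers(1_000, 150_000_000, size=n_genes)
    annotation = pd.DataFrame(
        {"chromosome": chrom, "start": start, "end": start + rng.integers(1_000, 100_000, n_genes)},
        index=genes,
    )
    return CountMatrix(
        counts=counts,
        annotation=annotation,
        groups=groups,
        true_fold=pd.Series(fold, index=genes, name="true_fold"),
    )
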