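"""Infer transgene-insertion architecture from paired-end alignments.

Given read alignments over a host chromosome and transgene unit contigs,
the mapper recovers the four features of a concatemeric insertion:

1. the target-site duplication, as a contiguous read-depth gain on the host
   (two extra copies in a homozygote double the local depth);
2. the two host/transgene junctions, from discordant ("chimeric") pairs
   with one mate on the host and one on a transgene contig;
3. the per-allele copy number of each transgene unit, from normalised
   transgene-contig depth;
4. the total insertion size, as sum(copies x unit length).

The front door is :class:`InsertionMapper`, a scikit-learn-style estimator
(``fit`` then read the trailing-underscore attributes); the module-level
functions expose each stage individually.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "DepthProfile",
    "DuplicationCall",
    "ChimericPair",
    "JunctionCall",
    "InsertionReport",
    "InsertionMapper",
    "compute_depth",
    "detect_duplication",
    "collect_chimeric_pairs",
    "call_junctions",
    "estimate_copies_and_size",
    "genotype_from_band_ratio",
    "load_alignments_sam",
]

# Zygosity thresholds on the duplication depth ratio: a homozygous
# duplication doubles depth (~2), a heterozygous one adds one copy over two
# alleles (~1.5).
HOM_RATIO = 1.75
HET_RATIO_MIN = 1.3


@dataclass
class DepthProfile:
    """Windowed read-start counts per contig, normalised to the host
    baseline (median host-window count)."""

    window: int
    raw: dict[str, np.ndarray]
    baseline: float

    @property
    def normalized(self) -> dict[str, np.ndarray]:
        return {c: r / self.baseline for c, r in self.raw.items()}

    def total_reads(self) -> int:
        return int(sum(r.sum() for r in self.raw.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for contig, raw in self.raw.items():
            for i, r in enumerate(raw):
                rows.append((contig, i * self.window, (i + 1) * self.window, r, r / self.baseline))
        return pd.DataFrame(rows, columns=["contig", "start", "end", "raw", "normalized"])


@dataclass(frozen=True)
class DuplicationCall:
    contig: str
    start: int
    end: int
    mean_depth: float  # normalised
    copy_ratio: float
    zygosity: str  # 'hom' | 'het'

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class ChimericPair:
    read: str
    host_pos: int
    host_strand: str
    transgene_contig: str
    transgene_pos: int


@dataclass(frozen=True)
class JunctionCall:
    side: str  # 'left' | 'right'
    breakpoint: float  # host coordinate
    uncertainty: float  # +/- bases
    support: int
    unit: str  # adjoining transgene unit contig


@dataclass
class InsertionReport:
    duplication: DuplicationCall | None
    left_junction: JunctionCall | None
    right_junction: JunctionCall | None
    unit_copies: dict[str, float]
    unit_copies_rounded: dict[str, int]
    total_size: int
    total_size_raw: float
    zygosity: str

    def to_json(self) -> str:
        d = {
            "duplication": asdict(self.duplication) if self.duplication else None,
            "left_junction": asdict(self.left_junction) if self.left_junction else None,
            "right_junction": asdict(self.right_junction) if self.right_junction else None,
            "unit_copies": self.unit_copies,
            "unit_copies_rounded": self.unit_copies_rounded,
            "total_size": self.total_size,
            "total_size_raw": self.total_size_raw,
            "zygosity": self.zygosity,
        }
        return json.dumps(d, indent=1)


def load_alignments_sam(path: str | Path) -> tuple[pd.DataFrame, dict[str, int]]:
    """Read a SAM/BAM file into the alignment table the mapper consumes."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), check_sq=False) as f:
        lengths = dict(zip(f.references, f.lengths))
        for r in f:
            if r.is_secondary or r.is_supplementary:
                continue
            rows.append(
                (
                    r.query_name,
                    1 if r.is_read1 else 2,
                    r.reference_name if not r.is_unmapped else None,
                    float(r.reference_start) if not r.is_unmapped else np.nan,
                    "-" if r.is_reverse else "+",
                    not r.is_unmapped,
                    r.next_reference_name if not r.mate_is_unmapped else None,
                    float(r.next_reference_start) if not r.mate_is_unmapped else np.nan,
                    not r.mate_is_unmapped,
                    float(r.template_length) if r.template_length else np.nan,
                    r.is_proper_pair,
                )
            )
    from .synthio import ALIGNMENT_COLUMNS

    return pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS), lengths


def compute_depth(
    alignments: pd.DataFrame,
    window: int = 1000,
    host_contigs: Sequence[str] | None = None,
    contig_lengths: Mapping[str, int] | None = None,
) -> DepthProfile:
    """Bin mapped read starts into fixed windows per contig and normalise to
    the median host-window depth.

    The baseline is robust to the duplication itself (26/2000 windows in the
    reference use case cannot move a median).  The sum of raw counts equals
    the number of mapped reads consumed.
    """
    if window < 100:
        raise ValueError("window must be >= 100 bases")
    if alignments.empty:
        raise ValueError("empty alignment stream")
    mapped = alignments[alignments["mapped"].astype(bool)]
    if mapped.empty:
        raise ValueError("no mapped reads in alignment stream")

    raw: dict[str, np.ndarray] = {}
    for contig, grp in mapped.groupby("contig", sort=False):
        pos = grp["pos"].to_numpy(float).astype(np.int64)
        if contig_lengths and contig in contig_lengths:
            n_win = max(int(np.ceil(contig_lengths[contig] / window)), 1)
        else:
            n_win = int(pos.max() // window) + 1
        raw[str(contig)] = np.bincount(pos // window, minlength=n_win).astype(float)
    if contig_lengths:
        for contig, length in contig_lengths.items():
            raw.setdefault(contig, np.zeros(max(int(np.ceil(length / window)), 1)))

    if host_contigs is None:
        host_contigs = list(raw)
    host_windows = np.concatenate([raw[c] for c in host_contigs if c in raw])
    baseline = float(np.median(host_windows))
    if baseline <= 0:
        raise ValueError("host baseline depth is zero")
    return DepthProfile(window=window, raw=raw, baseline=baseline)


def detect_duplication(
    profile: DepthProfile,
    min_length: int = 10_000,
    ratio_window: tuple[float, float] = (1.3, 2.7),
    contigs: Sequence[str] | None = None,
) -> list[DuplicationCall]:
    """Call duplications as maximal runs of consecutive windows whose
    normalised depth falls inside ``ratio_window``, at least ``min_length``
    long, snapped to window boundaries."""
    lo, hi = ratio_window
    calls: list[DuplicationCall] = []
    norm = profile.normalized
    for contig in contigs if contigs is not None else norm:
        d = norm[contig]
        inside = (d >= lo) & (d <= hi)
        # maximal runs of True
        edges = np.diff(np.concatenate([[0], inside.view(np.int8), [0]]))
        starts = np.nonzero(edges == 1)[0]
        ends = np.nonzero(edges == -1)[0]
        for s, e in zip(starts, ends):
            if (e - s) * profile.window < min_length:
                continue
            mean_depth = float(d[s:e].mean())
            zygosity = "hom" if mean_depth >= HOM_RATIO else "het"
            calls.append(
                DuplicationCall(
                    contig=contig,
                    start=int(s * profile.window),
                    end=int(e * profile.window),
                    mean_depth=mean_depth,
                    copy_ratio=mean_depth,
                    zygosity=zygosity,
                )
            )
    return calls


def collect_chimeric_pairs(
    alignments: pd.DataFrame,
    host_contig: str,
    transgene_contigs: Sequence[str],
) -> list[ChimericPair]:
    """Extract exactly the non-proper pairs with one mate on the host contig
    and the other on a transgene contig (one record per pair, keyed by the
    host-side read)."""
    tg = set(transgene_contigs)
    a = alignments
    sel = (
        a["mapped"].astype(bool)
        & a["mate_mapped"].astype(bool)
        & ~a["proper"].astype(bool)
        & (a["contig"] == host_contig)
        & a["mate_contig"].isin(tg)
    )
    out = [
        ChimericPair(
            read=str(r.read),
            host_pos=int(r.pos),
            host_strand=str(r.strand),
            transgene_contig=str(r.mate_contig),
            transgene_pos=int(r.mate_pos),
        )
        for r in a[sel].itertuples()
    ]
    return out


def call_junctions(
    pairs: Sequence[ChimericPair],
    dup: DuplicationCall | None = None,
    insert_mean: float = 400.0,
    insert_sd: float = 35.0,
    read_len: int = 100,
    min_support: int = 5,
) -> tuple[JunctionCall, JunctionCall]:
    """Cluster chimeric pairs into the two insertion junctions.

    Host-side reads on the forward strand face the array from the left; the
    left breakpoint is their innermost (rightmost) end extended by half the
    unread fragment interior, (insert_mean - 2*read_len)/2.  Reverse-strand
    host reads mirror this on the right.  With a duplication call, the two
    breakpoints must bracket or abut its interval within one insert length.
    """
    left = [p for p in pairs if p.host_strand == "+"]
    right = [p for p in pairs if p.host_strand == "-"]
    if len(left) < min_support or len(right) < min_support:
        raise ValueError(
            "insufficient junction evidence: "
            f"{len(left)} left / {len(right)} right pairs (need {min_support})"
        )
    offset = (insert_mean - 2 * read_len) / 2.0

    def majority_unit(group: Sequence[ChimericPair]) -> str:
        units = pd.Series([p.transgene_contig for p in group])
        return str(units.mode().iloc[0])

    left_bp = max(p.host_pos for p in left) + read_len + offset
    right_bp = min(p.host_pos for p in right) - offset
    lj = JunctionCall(
        side="left", breakpoint=left_bp, uncertainty=insert_sd,
        support=len(left), unit=majority_unit(left),
    )
    rj = JunctionCall(
        side="right", breakpoint=right_bp, uncertainty=insert_sd,
        support=len(right), unit=majority_unit(right),
    )
    if dup is not None:
        if not (
            lj.breakpoint >= dup.end - insert_mean
            and rj.breakpoint <= dup.start + insert_mean
        ):
            raise ValueError(
                "junction breakpoints do not bracket the duplication interval "
                f"({rj.breakpoint:.0f}, {lj.breakpoint:.0f}) vs "
                f"[{dup.start}, {dup.end})"
            )
    return lj, rj


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def estimate_copies_and_size(
    profile: DepthProfile,
    zygosity: str,
    unit_lengths: Mapping[str, int],
    duplication: DuplicationCall | None = None,
    junctions: tuple[JunctionCall, JunctionCall] | None = None,
) -> InsertionReport:
    """Estimate per-allele transgene copy number and total insertion size.

    A host window at baseline depth represents two allele copies, so a unit
    present at ``c`` copies per carrier allele on ``n`` carrier alleles shows
    normalised depth ``c*n/2``; copies per allele are therefore
    ``depth * 2 / n``.  Total size is sum(copies x unit length); both the
    raw and the half-up-rounded integer estimates are reported.
    """
    if zygosity == "hom":
        carriers = 2
    elif zygosity == "het":
        carriers = 1
    else:
        if duplication is not None:
            zygosity = duplication.zygosity
            carriers = 2 if zygosity == "hom" else 1
        else:
            raise ValueError("zygosity unknown and not inferable from duplication ratio")

    norm = profile.normalized
    copies: dict[str, float] = {}
    rounded: dict[str, int] = {}
    for unit, length in unit_lengths.items():
        depth = float(norm[unit].mean()) if unit in norm else 0.0
        c = depth * 2.0 / carriers
        copies[unit] = c
        rounded[unit] = _round_half_up(c)
    total_raw = float(sum(copies[u] * unit_lengths[u] for u in unit_lengths))
    total = int(sum(rounded[u] * unit_lengths[u] for u in unit_lengths))
    lj, rj = junctions if junctions is not None else (None, None)
    return InsertionReport(
        duplication=duplication,
        left_junction=lj,
        right_junction=rj,
        unit_copies=copies,
        unit_copies_rounded=rounded,
        total_size=total,
        total_size_raw=total_raw,
        zygosity=zygosity,
    )


def genotype_from_band_ratio(
    tg_signal: float, chr_signal: float, het_calibration_ratio: float
) -> int:
    """Transgenic allele count from semi-quantitative band densitometry.

    The transgene-specific band density is normalised to a chromosomal
    amplicon outside the duplicated region and scaled by the same ratio
    measured in a known heterozygote; 0/1/2 map to wild-type/het/hom.
    """
    if tg_signal < 0 or chr_signal < 0:
        raise ValueError("band densities must be non-negative")
    if chr_signal == 0:
        raise ValueError("chromosomal reference signal must be positive")
    if het_calibration_ratio <= 0:
        raise ValueError("calibration ratio must be positive")
    return _round_half_up((tg_signal / chr_signal) / het_calibration_ratio)


class InsertionMapper(BaseEstimator):
    """End-to-end insertion-architecture caller.

    Parameters
    ----------
    window : depth-profile window size in bases.
    min_dup_length : minimum duplication call length in bases.
    ratio_window : normalised-depth band accepted as a duplication.
    min_support : minimum chimeric pairs per junction.
    insert_mean, insert_sd, read_len : library geometry used for breakpoint
        extension and uncertainty.

    After ``fit`` the following attributes are set:

    ``depth_`` : :class:`DepthProfile`
    ``duplications_`` : list of :class:`DuplicationCall` on the host
    ``chimeric_pairs_`` : list of :class:`ChimericPair`
    ``junctions_`` : (left, right) :class:`JunctionCall`
    ``report_`` : :class:`InsertionReport`
    """

    def __init__(
        self,
        window: int = 1000,
        min_dup_length: int = 10_000,
        ratio_window: tuple[float, float] = (1.3, 2.7),
        min_support: int = 5,
        insert_mean: float = 400.0,
        insert_sd: float = 35.0,
        read_len: int = 100,
    ):
        self.window = window
        self.min_dup_length = min_dup_length
        self.ratio_window = ratio_window
        self.min_support = min_support
        self.insert_mean = insert_mean
        self.insert_sd = insert_sd
        self.read_len = read_len

    def fit(
        self,
        alignments: pd.DataFrame,
        y=None,
        *,
        host_contig: str,
        transgene_contigs: Sequence[str],
        unit_lengths: Mapping[str, int],
        contig_lengths: Mapping[str, int] | None = None,
    ) -> "InsertionMapper":
        self.depth_ = compute_depth(
            alignments,
            window=self.window,
            host_contigs=[host_contig],
            contig_lengths=contig_lengths,
        )
        self.duplications_ = detect_duplication(
            self.depth_,
            min_length=self.min_dup_length,
            ratio_window=self.ratio_window,
            contigs=[host_contig],
        )
        dup = self.duplications_[0] if self.duplications_ else None
        self.chimeric_pairs_ = collect_chimeric_pairs(
            alignments, host_contig, transgene_contigs
        )
        self.junctions_ = call_junctions(
            self.chimeric_pairs_,
            dup=dup,
            insert_mean=self.insert_mean,
            insert_sd=self.insert_sd,
            read_len=self.read_len,
            min_support=self.min_support,
        )
        zygosity = dup.zygosity if dup is not None else "unknown"
        self.report_ = estimate_copies_and_size(
            self.depth_,
            zygosity=zygosity,
            unit_lengths=unit_lengths,
            duplication=dup,
            junctions=self.junctions_,
        )
        return self
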