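"""Allele-specific CNV curation and the subclone-model input bundle.

Implements the two-pass curation protocol over germline-heterozygous-SNP
allelic counts: a first segmentation pass at threshold 0.3, an automated
curation rule keeping regions where any sample shows major copy number
> 2 or minor copy number < 0.5, estimation of a common breakpoint pair
across all tumors (median boundary snapped to the nearest het SNP), and
a second pass at threshold 0.2 inside the fixed boundaries.  The
segmenter itself is a deliberately simple two-channel binary
segmentation (normalized depth ratio + mirrored BAF) standing in for a
full bivariate changepoint model; the protocol around it — thresholds,
curation rule, breakpoint snapping, and the W_M / W_m / eps_M / eps_m
output matrices — is preserved.

Coordinates are 1-based inclusive throughout (VCF convention); the BED
export converts to 0-based half-open.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

FIRST_PASS_THRESHOLD = 0.3
SECOND_PASS_THRESHOLD = 0.2
MIN_SNPS_PER_CHROM = 10
MIN_SEGMENT_SNPS = 10

NO_CNV_COLUMN = "no_curated_cnv"


@dataclass
class HetSnpCounts:
    """Allelic depths at germline-heterozygous SNPs, tumors plus normal."""

    chrom: np.ndarray  # (n,) str
    pos: np.ndarray    # (n,) 1-based
    normal_a: np.ndarray
    normal_b: np.ndarray
    tumor: dict[str, tuple[np.ndarray, np.ndarray]]  # sample -> (a, b)

    def __post_init__(self):
        n = len(self.pos)
        for arr in (self.chrom, self.normal_a, self.normal_b):
            if len(arr) != n:
                raise ConfigurationError("het-SNP arrays have mismatched lengths")
        for sample, (a, b) in self.tumor.items():
            if len(a) != n or len(b) != n:
                raise ConfigurationError(f"het-SNP arrays for {sample!r} mismatched")
            if (a < 0).any() or (b < 0).any():
                raise ConfigurationError(f"negative depths for {sample!r}")

    @property
    def samples(self) -> list[str]:
        return list(self.tumor)

    @property
    def n_snps(self) -> int:
        return len(self.pos)

    def to_frame(self) -> pd.DataFrame:
        data = {"chrom": self.chrom, "pos": self.pos,
                "normal_a": self.normal_a, "normal_b": self.normal_b}
        for s, (a, b) in self.tumor.items():
            data[f"{s}_a"] = a
            data[f"{s}_b"] = b
        return pd.DataFrame(data)

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def read_tsv(cls, path) -> "HetSnpCounts":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        samples = sorted({c[:-2] for c in df.columns if c.endswith("_a")
                          and c not in ("normal_a",)})
        return cls(
            chrom=df["chrom"].to_numpy(dtype=object),
            pos=df["pos"].to_numpy(dtype=np.int64),
            normal_a=df["normal_a"].to_numpy(dtype=np.int64),
            normal_b=df["normal_b"].to_numpy(dtype=np.int64),
            tumor={s: (df[f"{s}_a"].to_numpy(dtype=np.int64),
                       df[f"{s}_b"].to_numpy(dtype=np.int64)) for s in samples},
        )


@dataclass
class CnvSegment:
    """A genomic segment with per-sample allele-specific copy numbers.

    ``major``/``minor`` map sample -> copy number (major >= minor >= 0);
    ``se_major``/``se_minor`` are the standard errors of those estimates.
    """

    chrom: str
    start: int  # 1-based inclusive
    end: int
    major: dict[str, float] = field(default_factory=dict)
    minor: dict[str, float] = field(default_factory=dict)
    se_major: dict[str, float] = field(default_factory=dict)
    se_minor: dict[str, float] = field(default_factory=dict)
    n_snps: int = 0

    def __post_init__(self):
        if self.end < self.start:
            raise ConfigurationError(f"segment end < start at {self.chrom}:{self.start}")
        for s in self.major:
            if self.major[s] < self.minor.get(s, 0.0) - 1e-9:
                raise ConfigurationError(f"major < minor for sample {s!r}")

    def deviation(self, sample: str) -> float:
        """Allele-specific deviation from the diploid one-copy state."""
        return max(abs(self.major[sample] - 1.0), abs(self.minor[sample] - 1.0))

    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class CnvInputBundle:
    """Curated segments plus the matrices the subclone model consumes.

    ``Y`` is the mutation x (segments + 1) one-hot overlap matrix whose
    final column flags mutations outside every curated region; ``wm`` /
    ``wmin`` / ``eps_m`` / ``eps_min`` are segments x samples matrices of
    major/minor copy numbers and their standard errors; ``rdep`` maps
    sample -> tumor/normal aligned-read ratio.
    """

    segments: list[CnvSegment]
    Y: pd.DataFrame
    wm: pd.DataFrame
    wmin: pd.DataFrame
    eps_m: pd.DataFrame
    eps_min: pd.DataFrame
    rdep: dict[str, float]

    def __post_init__(self):
        if not np.all(self.Y.sum(axis=1) == 1):
            raise ConfigurationError("Y rows must be one-hot")
        for s, r in self.rdep.items():
            if r <= 0:
                raise ConfigurationError(f"rdep must be positive for {s!r}")

    def write(self, out_dir) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [("Y", self.Y), ("W_major", self.wm), ("W_minor", self.wmin),
                         ("eps_major", self.eps_m), ("eps_minor", self.eps_min)]:
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", float_format="%.6g")
            paths[name] = p
        meta = {
            "rdep": {k: round(v, 8) for k, v in self.rdep.items()},
            "segments": [
                {"chrom": s.chrom, "start": s.start, "end": s.end, "n_snps": s.n_snps}
                for s in self.segments
            ],
        }
        p = out_dir / "bundle.json"
        p.write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")
        paths["meta"] = p
        return paths


def compute_rdep(tumor_read_total: float, normal_read_total: float) -> float:
    """Tumor/normal aligned-read ratio used to normalize depth ratios."""
    if normal_read_total <= 0:
        raise ValueError("normal read total must be positive")
    if tumor_read_total <= 0:
        raise ValueError("tumor read total must be positive")
    return tumor_read_total / normal_read_total


def rdep_from_snps(snps: HetSnpCounts) -> dict[str, float]:
    normal_total = float((snps.normal_a + snps.normal_b).sum())
    return {s: compute_rdep(float((a + b).sum()), normal_total)
            for s, (a, b) in snps.tumor.items()}


def _signals(snps: HetSnpCounts, sample: str, rdep: float):
    a, b = snps.tumor[sample]
    tumor_tot = (a + b).astype(float)
    normal_tot = (snps.normal_a + snps.normal_b).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        dr = np.where(normal_tot > 0, tumor_tot / np.maximum(normal_tot, 1), np.nan) / rdep
        baf = np.where(tumor_tot > 0, a / np.maximum(tumor_tot, 1), np.nan)
    mbaf = np.maximum(baf, 1 - baf)
    return dr, mbaf


def _binary_segment(z: np.ndarray, penalty: float,
                    min_size: int = MIN_SEGMENT_SNPS,
                    max_segments: int = 20) -> list[tuple[int, int]]:
    """Recursive binary segmentation of standardized channels (n, c).

    Splits greedily at the point with the largest reduction in summed
    squared deviation from segment means; a split is accepted when the
    gain exceeds ``penalty``.  Returns half-open index intervals.
    """
    n = z.shape[0]
    segments: list[tuple[int, int]] = []
    queue = [(0, n)]
    while queue and len(segments) + len(queue) < max_segments + 1:
        lo, hi = queue.pop()
        seg = z[lo:hi]
        L = hi - lo
        if L < 2 * min_size:
            segments.append((lo, hi))
            continue
        csum = np.cumsum(seg, axis=0)
        total = csum[-1]
        k = np.arange(min_size, L - min_size + 1, dtype=float)  # left sizes
        left = csum[min_size - 1:L - min_size]
        # cost reduction from splitting at k: ||left mean||^2 terms
        gain = (left**2 / k[:, None] + (total - left)**2 / (L - k)[:, None]
                - total**2 / L).sum(axis=1)
        best = int(np.argmax(gain))
        if gain[best] > penalty:
            split = lo + min_size + best
            queue.append((lo, split))
            queue.append((split, hi))
        else:
            segments.append((lo, hi))
    segments.extend(queue)
    return sorted(segments)


def _estimate_segment(dr: np.ndarray, mbaf: np.ndarray):
    """Per-segment (t, f) -> (M, m) with delta-method standard errors."""
    dr = dr[~np.isnan(dr)]
    mbaf_ = mbaf[~np.isnan(mbaf)]
    L = max(len(dr), 1)
    Lb = max(len(mbaf_), 1)
    t = 2.0 * float(np.mean(dr)) if len(dr) else 2.0
    f = float(np.mean(mbaf_)) if len(mbaf_) else 0.5
    se_t = 2.0 * float(np.std(dr, ddof=1)) / np.sqrt(L) if len(dr) > 1 else 0.1
    se_f = float(np.std(mbaf_, ddof=1)) / np.sqrt(Lb) if len(mbaf_) > 1 else 0.05
    M = t * f
    m = t * (1 - f)
    se_M = float(np.hypot(f * se_t, t * se_f))
    se_m = float(np.hypot((1 - f) * se_t, t * se_f))
    return M, m, max(se_M, 1e-6), max(se_m, 1e-6)


def segment_allelic(
    snps: HetSnpCounts,
    threshold: float = FIRST_PASS_THRESHOLD,
    rdep: Mapping[str, float] | None = None,
    penalty_scale: float = 6.0,
) -> dict[str, list[CnvSegment]]:
    """First-pass per-sample allele-specific segmentation.

    Each tumor sample is segmented independently per chromosome on two
    standardized channels: the rdep-normalized tumor/normal depth ratio
    and the mirrored BAF.  Per segment, total copy number
    t = 2 * mean(depth ratio) and major-allele frequency f = mean
    mirrored BAF give M = t*f and m = t*(1-f) with delta-method standard
    errors.  A segment is reported only when
    max(|M - 1|, |m - 1|) > threshold.  Chromosomes with fewer than
    10 SNPs are skipped with a warning.
    """
    if rdep is None:
        rdep = rdep_from_snps(snps)
    out: dict[str, list[CnvSegment]] = {s: [] for s in snps.samples}
    for chrom in pd.unique(snps.chrom):
        idx = np.flatnonzero(snps.chrom == chrom)
        if np.any(np.diff(snps.pos[idx]) < 0):
            raise ConfigurationError(f"SNPs on chromosome {chrom} are not sorted")
        if len(idx) < MIN_SNPS_PER_CHROM:
            warnings.warn(f"chromosome {chrom}: only {len(idx)} het SNPs, skipped")
            continue
        for sample in snps.samples:
            dr, mbaf = _signals(snps, sample, rdep[sample])
            dr_c, mbaf_c = dr[idx], mbaf[idx]
            # robust per-channel scale for standardization
            def _scale(x):
                x = x[~np.isnan(x)]
                mad = np.median(np.abs(x - np.median(x))) * 1.4826 if len(x) else 1.0
                return max(mad, 1e-6)
            z = np.column_stack([
                np.nan_to_num((dr_c - np.nanmedian(dr_c)) / _scale(dr_c)),
                np.nan_to_num((mbaf_c - np.nanmedian(mbaf_c)) / _scale(mbaf_c)),
            ])
            penalty = penalty_scale * z.shape[1] * np.log(len(idx))
            for lo, hi in _binary_segment(z, penalty):
                M, m, se_M, se_m = _estimate_segment(dr_c[lo:hi], mbaf_c[lo:hi])
                if max(abs(M - 1.0), abs(m - 1.0)) > threshold:
                    out[sample].append(CnvSegment(
                        chrom=str(chrom),
                        start=int(snps.pos[idx[lo]]),
                        end=int(snps.pos[idx[hi - 1]]),
                        major={sample: M}, minor={sample: m},
                        se_major={sample: se_M}, se_minor={sample: se_m},
                        n_snps=hi - lo,
                    ))
    return out


def curate_segments(segments: Mapping[str, Sequence[CnvSegment]]) -> list[CnvSegment]:
    """Automated curation: keep maximal regions where any sample shows
    major copy number > 2 or minor copy number < 0.5.

    Qualifying per-sample segments are merged (union of overlapping
    intervals per chromosome) into maximal disjoint regions.
    """
    qualifying = []
    for sample, segs in segments.items():
        for seg in segs:
            if seg.major[sample] > 2.0 or seg.minor[sample] < 0.5:
                qualifying.append(seg)
    by_chrom: dict[str, list[CnvSegment]] = {}
    for seg in qualifying:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    curated = []
    for chrom in sorted(by_chrom):
        intervals = sorted((s.start, s.end) for s in by_chrom[chrom])
        merged = [list(intervals[0])]
        for start, end in intervals[1:]:
            if start <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], end)
            else:
                merged.append([start, end])
        curated.extend(CnvSegment(chrom=chrom, start=s, end=e) for s, e in merged)
    return curated


def harmonize_breakpoints(
    curated: Sequence[CnvSegment],
    segments: Mapping[str, Sequence[CnvSegment]],
    snps: HetSnpCounts,
    threshold: float = SECOND_PASS_THRESHOLD,
    rdep: Mapping[str, float] | None = None,
) -> list[CnvSegment]:
    """Second curation pass: common breakpoints, then re-estimation.

    For each curated region, the common start (end) is the median of the
    overlapping per-sample segment starts (ends), snapped to the nearest
    het SNP position.  M, m and their standard errors are then
    re-estimated for every sample inside the fixed boundaries; the
    region is kept when any sample's allele-specific deviation exceeds
    ``threshold``.  Regions spanned by no SNP are dropped with a warning.
    """
    if rdep is None:
        rdep = rdep_from_snps(snps)
    signals = {s: _signals(snps, s, rdep[s]) for s in snps.samples}
    out: list[CnvSegment] = []
    for region in curated:
        starts, ends = [], []
        for sample, segs in segments.items():
            for seg in segs:
                if seg.chrom == region.chrom and seg.start <= region.end and seg.end >= region.start:
                    starts.append(seg.start)
                    ends.append(seg.end)
        if not starts:
            starts, ends = [region.start], [region.end]
        chrom_idx = np.flatnonzero(snps.chrom == region.chrom)
        if len(chrom_idx) == 0:
            warnings.warn(f"region {region.label()}: no het SNPs on chromosome, dropped")
            continue
        pos = snps.pos[chrom_idx]
        start = int(pos[np.argmin(np.abs(pos - np.median(starts)))])
        end = int(pos[np.argmin(np.abs(pos - np.median(ends)))])
        if end < start:
            start, end = end, start
        inside = chrom_idx[(pos >= start) & (pos <= end)]
        if len(inside) == 0:
            warnings.warn(f"region {region.label()}: no spanning SNP, dropped")
            continue
        seg = CnvSegment(chrom=region.chrom, start=start, end=end, n_snps=len(inside))
        for sample in snps.samples:
            dr, mbaf = signals[sample]
            M, m, se_M, se_m = _estimate_segment(dr[inside], mbaf[inside])
            seg.major[sample] = M
            seg.minor[sample] = m
            seg.se_major[sample] = se_M
            seg.se_minor[sample] = se_m
        if max(seg.deviation(s) for s in snps.samples) > threshold:
            out.append(seg)
    return out


def run_two_pass_curation(
    snps: HetSnpCounts,
    first_threshold: float = FIRST_PASS_THRESHOLD,
    second_threshold: float = SECOND_PASS_THRESHOLD,
    rdep: Mapping[str, float] | None = None,
) -> list[CnvSegment]:
    """The full protocol: pass 1 -> curation rule -> common breakpoints -> pass 2."""
    if rdep is None:
        rdep = rdep_from_snps(snps)
    first = segment_allelic(snps, threshold=first_threshold, rdep=rdep)
    curated = curate_segments(first)
    return harmonize_breakpoints(curated, first, snps,
                                 threshold=second_threshold, rdep=rdep)


def build_bundle(curated: Sequence[CnvSegment], matrix, rdep: Mapping[str, float] | None = None,
                 samples: Sequence[str] | None = None) -> CnvInputBundle:
    """Assemble the subclone-model input bundle from curated segments.

    ``Y[v, s]`` is 1 when variant v lies within segment s (1-based
    inclusive overlap); variants outside every curated region get the
    final no-CNV column.  Curated regions must be disjoint.
    """
    segs = sorted(curated, key=lambda s: (s.chrom, s.start))
    for a, b in zip(segs, segs[1:]):
        if a.chrom == b.chrom and b.start <= a.end:
            raise ConfigurationError(
                f"curated regions overlap: {a.label()} and {b.label()}")
    if samples is None:
        samples = sorted({s for seg in segs for s in seg.major}) if segs else []
        if not samples and hasattr(matrix, "tumor_samples"):
            samples = matrix.tumor_samples
    labels = [s.label() for s in segs] + [NO_CNV_COLUMN]

    variants = matrix.variants if hasattr(matrix, "variants") else list(matrix)
    ids = [matrix.variant_label(i) for i in range(len(variants))] \
        if hasattr(matrix, "variant_label") else [f"v{i}" for i in range(len(variants))]
    Y = np.zeros((len(variants), len(labels)), dtype=int)
    for vi, var in enumerate(variants):
        hit = None
        for si, seg in enumerate(segs):
            if var.chrom == seg.chrom and seg.start <= var.pos <= seg.end:
                hit = si
                break
        Y[vi, hit if hit is not None else -1] = 1
    Ydf = pd.DataFrame(Y, index=ids, columns=labels)

    def _mat(getter, default):
        data = {s.label(): [getter(s).get(smp, default) for smp in samples] for s in segs}
        return pd.DataFrame(data, index=list(samples)).T

    wm = _mat(lambda s: s.major, 1.0)
    wmin = _mat(lambda s: s.minor, 1.0)
    eps_m = _mat(lambda s: s.se_major, 0.1)
    eps_min = _mat(lambda s: s.se_minor, 0.1)
    if rdep is None:
        rdep = {s: 1.0 for s in samples}
    return CnvInputBundle(segments=segs, Y=Ydf, wm=wm, wmin=wmin,
                          eps_m=eps_m, eps_min=eps_min, rdep=dict(rdep))


def diploid_bundle(matrix) -> CnvInputBundle:
    """Trivial bundle with no curated regions (all mutations diploid)."""
    return build_bundle([], matrix, rdep={s: 1.0 for s in matrix.tumor_samples},
                        samples=matrix.tumor_samples)


def write_bed(curated: Sequence[CnvSegment], path) -> Path:
    """Curated regions as BED (0-based half-open)."""
    path = Path(path)
    lines = [f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.label()}" for s in curated]
    path.write_text("\n".join(lines) + ("\n" if lines else ""))
    return path


def write_regions_tsv(curated: Sequence[CnvSegment], path) -> Path:
    """Curated regions as native 1-based TSV with per-sample M/m."""
    path = Path(path)
    rows = []
    for seg in curated:
        for sample in seg.major:
            rows.append((seg.chrom, seg.start, seg.end, sample,
                         seg.major[sample], seg.minor[sample],
                         seg.se_major[sample], seg.se_minor[sample], seg.n_snps))
    pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "major",
                                "minor", "se_major", "se_minor", "n_snps"]) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")
    return path
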