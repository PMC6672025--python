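"""Cohort variant matrix: harmonized multi-sample somatic calls.

Reads multi-sample VCFs (FORMAT/AD) and long-format TSVs into a single
variants x samples count matrix with one designated normal sample, builds
per-sample presence sets (the S_i sets used for tree building), and
computes per-sample summaries: tumor mutational burden and sharing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ParseError

#: Exome capture territory (Mb) used to normalize mutation counts into
#: mutations per megabase.
DEFAULT_CAPTURE_MB = 38.9

_CHROM_RANK = {str(i): i for i in range(1, 23)} | {"X": 23, "Y": 24, "MT": 25, "M": 25}


def _chrom_key(chrom: str):
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    return (_CHROM_RANK.get(c, 99), c)


@dataclass(frozen=True)
class SomaticVariant:
    """One somatic variant in minimal (left-trimmed) representation."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")
        if not self.ref or not self.alt:
            raise ValueError(f"empty allele at {self.chrom}:{self.pos}")

    @property
    def vclass(self) -> str:
        return "SNV" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)

    def sort_key(self) -> tuple:
        return (_chrom_key(self.chrom), self.pos, self.ref, self.alt)

    def normalized(self) -> "SomaticVariant":
        """Minimal representation: trim shared suffix, then shared prefix.

        This is reference-free left-normalization of the allele pair; it
        prevents spurious set differences between equivalent indel
        encodings (e.g. ``ATT>AT`` vs ``TT>T`` at the next base).
        """
        ref, alt, pos = self.ref, self.alt, self.pos
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return SomaticVariant(self.chrom, pos, ref, alt)


@dataclass
class CohortVariantMatrix:
    """Somatic variants x samples with allelic depths and presence sets."""

    variants: list[SomaticVariant]
    samples: list[str]
    normal_sample: str
    alt_counts: np.ndarray  # (M, S) int
    ref_counts: np.ndarray  # (M, S) int
    presence: np.ndarray | None = None  # (M, S) bool
    variant_ids: list[str] | None = None
    expected_vaf: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        M, S = len(self.variants), len(self.samples)
        if self.alt_counts.shape != (M, S) or self.ref_counts.shape != (M, S):
            raise ConfigurationError("count matrix shapes do not match variants x samples")
        if (self.alt_counts < 0).any() or (self.ref_counts < 0).any():
            raise ConfigurationError("negative read counts")
        if self.normal_sample not in self.samples:
            raise ConfigurationError(f"normal sample {self.normal_sample!r} not in samples")

    @property
    def tumor_samples(self) -> list[str]:
        return [s for s in self.samples if s != self.normal_sample]

    @property
    def depth(self) -> np.ndarray:
        return self.alt_counts + self.ref_counts

    @property
    def vaf(self) -> np.ndarray:
        """alt / depth with NaN where depth is 0 (VAF undefined)."""
        depth = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(depth > 0, self.alt_counts / np.maximum(depth, 1), np.nan)
        return v

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise ConfigurationError(f"unknown sample {sample!r}") from None

    def variant_label(self, vi: int) -> str:
        if self.variant_ids:
            return self.variant_ids[vi]
        v = self.variants[vi]
        return f"{v.chrom}:{v.pos}:{v.ref}>{v.alt}"

    def presence_sets(self, snv_only: bool = False) -> dict[str, frozenset]:
        """Per-sample sets S_i of present variants (tumor samples only)."""
        if self.presence is None:
            raise ConfigurationError("presence not built; call build_presence_sets first")
        keep = np.array([v.vclass == "SNV" for v in self.variants]) if snv_only \
            else np.ones(len(self.variants), dtype=bool)
        out = {}
        for s in self.tumor_samples:
            si = self.sample_index(s)
            mask = self.presence[:, si] & keep
            out[s] = frozenset(self.variants[vi].key for vi in np.flatnonzero(mask))
        return out

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for vi, v in enumerate(self.variants):
            for si, s in enumerate(self.samples):
                rows.append((v.chrom, v.pos, v.ref, v.alt, s,
                             int(self.ref_counts[vi, si]), int(self.alt_counts[vi, si])))
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt",
                                           "sample", "ref_count", "alt_count"])

    def write_tsv(self, path) -> Path:
        path = Path(path)
        self.to_long_frame().to_csv(path, sep="\t", index=False)
        return path


def _read_manifest(manifest) -> tuple[list[str], str]:
    if isinstance(manifest, (str, Path)):
        df = pd.read_csv(manifest, sep="\t", dtype=str)
    else:
        df = pd.DataFrame(manifest)
    if not {"sample", "role"}.issubset(df.columns):
        raise ConfigurationError("manifest needs 'sample' and 'role' columns")
    normals = df.loc[df["role"] == "normal", "sample"].tolist()
    if len(normals) != 1:
        raise ConfigurationError(
            f"manifest must designate exactly one normal sample, found {len(normals)}")
    if df["sample"].duplicated().any():
        raise ConfigurationError("duplicate sample names in manifest")
    return df["sample"].tolist(), normals[0]


def _records_from_vcf(path) -> Iterable[tuple[SomaticVariant, str, int, int]]:
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    for rec in vcf:
        ad = rec.format("AD")
        if ad is None:
            raise ParseError(f"{path}: record {rec.CHROM}:{rec.POS} has no AD field")
        for ai, alt in enumerate(rec.ALT):
            if alt in (".", "", "*"):
                continue
            var = SomaticVariant(rec.CHROM, rec.POS, rec.REF, alt).normalized()
            for si, sample in enumerate(samples):
                row = ad[si]
                if len(row) <= ai + 1:
                    raise ParseError(
                        f"{path}: malformed AD for {sample} at {rec.CHROM}:{rec.POS}")
                r = int(row[0])
                a = int(row[ai + 1])
                # cyvcf2 encodes missing as large negative sentinels
                r = max(r, 0) if r > -2**30 else 0
                a = max(a, 0) if a > -2**30 else 0
                yield var, sample, r, a


def _records_from_tsv(path) -> Iterable[tuple[SomaticVariant, str, int, int]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = {"chrom", "pos", "ref", "alt", "sample", "ref_count", "alt_count"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: long TSV needs columns {sorted(required)}")
    for row in df.itertuples(index=False):
        try:
            var = SomaticVariant(str(row.chrom), int(row.pos),
                                 str(row.ref), str(row.alt)).normalized()
            yield var, str(row.sample), int(row.ref_count), int(row.alt_count)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: bad record {tuple(row)}: {exc}") from exc


def read_cohort(paths, manifest) -> CohortVariantMatrix:
    """Read one or more VCF/TSV files into a deduplicated cohort matrix.

    Variants are deduplicated on the normalized (chrom, pos, ref, alt)
    key across all inputs, sorted by genome coordinate; samples a file
    does not observe get depth 0.  The manifest must designate exactly
    one normal sample.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    samples, normal = _read_manifest(manifest)
    index: dict[tuple, int] = {}
    variants: list[SomaticVariant] = []
    counts: dict[tuple[int, str], tuple[int, int]] = {}
    for path in paths:
        path = Path(path)
        reader = _records_from_vcf if path.suffix.lower() == ".vcf" else _records_from_tsv
        for var, sample, r, a in reader(path):
            if sample not in samples:
                raise ConfigurationError(f"{path}: sample {sample!r} not in manifest")
            vi = index.get(var.key)
            if vi is None:
                vi = len(variants)
                index[var.key] = vi
                variants.append(var)
            prev = counts.get((vi, sample))
            if prev is not None and prev != (r, a):
                raise ParseError(
                    f"conflicting counts for {var.chrom}:{var.pos} {var.ref}>{var.alt} "
                    f"in sample {sample}")
            counts[(vi, sample)] = (r, a)

    order = sorted(range(len(variants)), key=lambda i: variants[i].sort_key())
    remap = {old: new for new, old in enumerate(order)}
    variants = [variants[i] for i in order]
    M, S = len(variants), len(samples)
    alt = np.zeros((M, S), dtype=np.int64)
    ref = np.zeros((M, S), dtype=np.int64)
    for (vi, sample), (r, a) in counts.items():
        si = samples.index(sample)
        ref[remap[vi], si] = r
        alt[remap[vi], si] = a
    matrix = CohortVariantMatrix(variants=variants, samples=samples,
                                 normal_sample=normal, alt_counts=alt, ref_counts=ref)
    build_presence_sets(matrix)
    return matrix


def build_presence_sets(matrix: CohortVariantMatrix,
                        min_alt: int = 4, min_vaf: float = 0.05) -> np.ndarray:
    """Mark a variant present in a sample when alt >= min_alt and VAF >= min_vaf.

    VAF is undefined at depth 0, which counts as absent.  The normal
    column is forced absent: the matrix holds somatic calls, so
    S_normal is empty by definition.
    """
    depth = matrix.depth
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, matrix.alt_counts / np.maximum(depth, 1), 0.0)
    presence = (matrix.alt_counts >= min_alt) & (vaf >= min_vaf) & (depth > 0)
    presence[:, matrix.sample_index(matrix.normal_sample)] = False
    matrix.presence = presence
    return presence


def compute_tmb(matrix: CohortVariantMatrix, sample: str,
                capture_mb: float = DEFAULT_CAPTURE_MB,
                include_indels: bool = True) -> float:
    """Tumor mutational burden: present mutations / capture megabases."""
    if capture_mb <= 0:
        raise ValueError(f"capture_mb must be positive, got {capture_mb}")
    if matrix.presence is None:
        raise ConfigurationError("presence not built; call build_presence_sets first")
    si = matrix.sample_index(sample)
    mask = matrix.presence[:, si].copy()
    if not include_indels:
        mask &= np.array([v.vclass == "SNV" for v in matrix.variants])
    return float(mask.sum()) / capture_mb


def sharing_summary(matrix: CohortVariantMatrix, snv_only: bool = False) -> dict:
    """Cohort sharing: per-sample counts, unique/total calls, pairwise Jaccard."""
    sets = matrix.presence_sets(snv_only=snv_only)
    names = list(sets)
    per_sample = {s: len(sets[s]) for s in names}
    union = set().union(*sets.values()) if sets else set()
    jaccard = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j, b in enumerate(names):
            if i < j:
                u = len(sets[a] | sets[b])
                val = len(sets[a] & sets[b]) / u if u else 1.0
                jaccard.iloc[i, j] = jaccard.iloc[j, i] = val
    return {
        "per_sample": per_sample,
        "total_calls": int(sum(per_sample.values())),
        "unique_variants": len(union),
        "jaccard": jaccard,
    }


def write_summary(summary: dict, out_prefix) -> tuple[Path, Path]:
    """Serialize a sharing summary as TSV (per-sample table) + JSON."""
    out_prefix = Path(out_prefix)
    tsv = out_prefix.with_suffix(".tsv")
    js = out_prefix.with_suffix(".json")
    pd.Series(summary["per_sample"], name="n_present").rename_axis("sample") \
        .to_frame().to_csv(tsv, sep="\t")
    payload = {
        "per_sample": summary["per_sample"],
        "total_calls": summary["total_calls"],
        "unique_variants": summary["unique_variants"],
        "jaccard": summary["jaccard"].round(6).to_dict(),
    }
    js.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return tsv, js
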