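"""Per-variant feature assembly: purifying-selection features in five
categories.

Category A holds interspecies conservation scores (GERP, PhastCons, PhyloP
at three evolutionary depths); category B holds recent/ongoing human
selection signals (background selection, windowed allele-frequency
statistics, site-frequency-spectrum neutrality tests, context-dependent
tolerance); category C holds gene-level constraint metrics; category D holds
sequence context (GC/CpG content and one-hot region flags); category E holds
epigenetic track lookups.

Position-level scores are consumed as precomputed interval tracks; windowed
allele-frequency statistics are computed here from a population panel,
always excluding the query variant itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .types import AnnotatedVariant, VariantRecord

POPULATIONS = ("global", "AFR", "AMR", "EAS", "FIN", "NFE", "OTH", "ASJ")

_NEUTRALITY = [
    f"{test}_{pop}_pvalue"
    for test in ("TajimasD", "FuLisD", "FuLisF")
    for pop in ("CEU", "CHB", "YRI")
]

CATEGORY_FEATURES: Dict[str, List[str]] = {
    "A": [
        "GerpN",
        "GerpS",
        "priPhCons",
        "mamPhCons",
        "verPhCons",
        "priPhyloP",
        "mamPhyloP",
        "verPhyloP",
    ],
    "B": [
        "bStatistic",
        "meanDaf1000G",
        "meanHet1000G",
        "meanMAF1000G",
        "meanMAFGnomAD",
        "meanMAF_AFRGnomAD",
        "meanMAF_AMRGnomAD",
        "meanMAF_EASGnomAD",
        "meanMAF_FINGnomAD",
        "meanMAF_NFEGnomAD",
        "meanMAF_OTHGnomAD",
        "meanMAF_ASJGnomAD",
        *_NEUTRALITY,
        "CDTS",
    ],
    "C": [
        "ncRVIS",
        "ncGERP",
        "dNdS",
        "pLI",
        "RVIS_percentile",
        "GDI",
        "familyMemberCount",
        "gene_age",
    ],
    "D": [
        "GC",
        "CpG",
        "region_intronic",
        "region_UTR5",
        "region_UTR3",
        "region_upstream",
        "region_downstream",
        "region_intergenic",
    ],
    "E": [
        "EncOCDNaseSig",
        "EncOCDNasePVal",
        "EncOCFaireSig",
        "EncOCFairePVal",
        "EncOCctcfSig",
        "EncOCctcfPVal",
        "EncOCpolIISig",
        "EncOCpolIIPVal",
        "EncOCmycSig",
        "EncOCmycPVal",
        "EncOCCombPVal",
        "EncOCC",
        "EncNucleo",
        "TFBS",
        "TFBSPeaks",
        "TFBSPeaksMax",
        "EncH3K4Me1",
        "EncH3K4Me3",
        "EncH3K27Ac",
    ],
}

#: Features served by position-indexed interval tracks.
TRACK_FEATURES = frozenset(
    CATEGORY_FEATURES["A"] + ["bStatistic", "CDTS"] + _NEUTRALITY + CATEGORY_FEATURES["E"]
)

#: Windowed allele-frequency features -> (statistic, population).
WINDOW_AF_FEATURES: Dict[str, Tuple[str, str]] = {
    "meanDaf1000G": ("meanDAF", "global"),
    "meanHet1000G": ("meanHet", "global"),
    "meanMAF1000G": ("meanMAF", "global"),
    "meanMAFGnomAD": ("meanMAF", "global"),
    **{f"meanMAF_{p}GnomAD": ("meanMAF", p) for p in POPULATIONS if p != "global"},
}

REGION_FLAGS = {
    "intronic": "region_intronic",
    "UTR5": "region_UTR5",
    "UTR3": "region_UTR3",
    "upstream": "region_upstream",
    "downstream": "region_downstream",
    "intergenic": "region_intergenic",
}


def feature_names(config: str) -> List[str]:
    """Ordered feature names for a category configuration like ``"ABCD"``."""
    letters = sorted(set(config.upper()))
    if not letters:
        raise ValueError("empty feature configuration")
    bad = [c for c in letters if c not in CATEGORY_FEATURES]
    if bad:
        raise ValueError(f"unknown feature categories: {bad}")
    out: List[str] = []
    for c in letters:
        out.extend(CATEGORY_FEATURES[c])
    return out


def feature_category(name: str) -> str:
    for cat, names in CATEGORY_FEATURES.items():
        if name in names:
            return cat
    raise KeyError(name)


class TrackError(ValueError):
    """Raised for malformed feature tracks."""


class FeatureTrack:
    """A position-indexed score track: sorted non-overlapping intervals.

    Intervals are 1-based closed; positions not covered by any interval look
    up as missing (NaN).
    """

    def __init__(
        self,
        name: str,
        data: Mapping[str, Tuple[np.ndarray, np.ndarray, np.ndarray]],
        resolution: Optional[int] = None,
    ):
        self.name = name
        self.resolution = resolution
        self._data: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, (starts, ends, values) in data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            if not (len(starts) == len(ends) == len(values)):
                raise TrackError(f"{name}/{chrom}: ragged arrays")
            if np.any(starts > ends):
                raise TrackError(f"{name}/{chrom}: interval start > end")
            if np.any(np.diff(starts) <= 0) or np.any(starts[1:] <= ends[:-1]):
                raise TrackError(f"{name}/{chrom}: intervals unsorted or overlapping")
            self._data[chrom] = (starts, ends, values)

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Iterable[Tuple[str, int, int, float]],
        resolution: Optional[int] = None,
    ) -> "FeatureTrack":
        by_chrom: Dict[str, List[Tuple[int, int, float]]] = {}
        for chrom, s, e, v in records:
            by_chrom.setdefault(chrom, []).append((s, e, v))
        data = {}
        for chrom, rows in by_chrom.items():
            rows.sort()
            s, e, v = zip(*rows)
            data[chrom] = (np.array(s), np.array(e), np.array(v))
        return cls(name, data, resolution)

    def lookup(self, chrom: str, pos: int) -> float:
        """Value of the interval containing ``pos``; NaN when uncovered."""
        entry = self._data.get(chrom)
        if entry is None:
            return float("nan")
        starts, ends, values = entry
        i = int(np.searchsorted(starts, pos, "right")) - 1
        if i >= 0 and ends[i] >= pos:
            return float(values[i])
        return float("nan")

    def plant(self, chrom: str, pos: int, value: float) -> None:
        """Override the score at a single base, splitting any covering bin."""
        starts, ends, values = self._data.get(chrom, (np.array([], dtype=np.int64),) * 3)
        i = int(np.searchsorted(starts, pos, "right")) - 1
        new: List[Tuple[int, int, float]] = []
        if i >= 0 and ends[i] >= pos:
            s, e, v = int(starts[i]), int(ends[i]), float(values[i])
            if s <= pos - 1:
                new.append((s, pos - 1, v))
            new.append((pos, pos, value))
            if pos + 1 <= e:
                new.append((pos + 1, e, v))
            starts = np.delete(starts, i)
            ends = np.delete(ends, i)
            values = np.delete(values, i)
        else:
            new.append((pos, pos, value))
        for s, e, v in new:
            j = int(np.searchsorted(starts, s))
            starts = np.insert(starts, j, s)
            ends = np.insert(ends, j, e)
            values = np.insert(values, j, v)
        self._data[chrom] = (starts, ends, values)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom in sorted(self._data):
            s, e, v = self._data[chrom]
            rows.append(pd.DataFrame({"chrom": chrom, "start": s, "end": e, "value": v}))
        return pd.concat(rows, ignore_index=True)

    def values_std(self) -> float:
        vals = np.concatenate([v for _, _, v in self._data.values()])
        return float(np.std(vals))


def lookup_track(track: FeatureTrack, chrom: str, pos: int) -> float:
    return track.lookup(chrom, pos)


class PopulationPanel:
    """A panel of population variants with per-population allele frequencies,
    indexed by chromosome and position for windowed statistics."""

    def __init__(self, frame: pd.DataFrame):
        required = {"chrom", "pos", "maf"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"panel missing columns: {sorted(missing)}")
        df = frame.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
        if (df["maf"].dropna() > 0.5).any() or (df["maf"].dropna() < 0).any():
            raise ValueError("panel MAF must be folded to [0, 0.5]")
        self.frame = df
        self._pos: Dict[str, np.ndarray] = {}
        self._cols: Dict[str, Dict[str, np.ndarray]] = {}
        colnames = ["maf", "daf"] + [
            f"maf_{p}" for p in POPULATIONS if p != "global" and f"maf_{p}" in df.columns
        ]
        for chrom, sub in df.groupby("chrom", sort=False):
            self._pos[chrom] = sub["pos"].to_numpy(np.int64)
            self._cols[chrom] = {
                c: sub[c].to_numpy(float) for c in colnames if c in sub.columns
            }

    def __len__(self) -> int:
        return len(self.frame)

    def window_arrays(
        self, chrom: str, lo: int, hi: int
    ) -> Tuple[np.ndarray, Dict[str, np.ndarray]]:
        pos = self._pos.get(chrom)
        if pos is None:
            return np.empty(0, dtype=np.int64), {}
        a = int(np.searchsorted(pos, lo, "left"))
        b = int(np.searchsorted(pos, hi, "right"))
        return pos[a:b], {c: v[a:b] for c, v in self._cols[chrom].items()}


def window_af_stat(
    variant: VariantRecord,
    panel: PopulationPanel,
    stat: str,
    population: str = "global",
    window_bp: int = 1000,
) -> float:
    """Mean allele-frequency statistic over panel variants within a window
    centred on the query (pos +/- window_bp/2 inclusive), always excluding
    any panel record at the query's own position.

    Returns NaN when no panel variant falls in the window.
    """
    if population not in POPULATIONS:
        raise ValueError(
            f"unknown population {population!r}; available: {list(POPULATIONS)}"
        )
    if stat not in ("meanMAF", "meanDAF", "meanHet"):
        raise ValueError(f"unknown statistic {stat!r}")
    half = window_bp // 2
    pos, cols = panel.window_arrays(variant.chrom, variant.pos - half, variant.pos + half)
    if len(pos) == 0:
        return float("nan")
    keep = pos != variant.pos
    if stat == "meanMAF":
        col = "maf" if population == "global" else f"maf_{population}"
        if col not in cols:
            raise ValueError(
                f"panel lacks {col!r}; available: {sorted(cols)}"
            )
        vals = cols[col][keep]
    elif stat == "meanDAF":
        if "daf" not in cols:
            return float("nan")
        vals = cols["daf"][keep]
    else:  # meanHet: expected heterozygosity 2p(1-p) from the site MAF
        p = cols["maf"][keep]
        vals = 2.0 * p * (1.0 - p)
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        return float("nan")
    return float(np.mean(vals))


def gc_cpg_content(
    chrom: str,
    pos: int,
    reference: Mapping[str, str],
    halfwidth: int = 75,
) -> Tuple[float, float]:
    """Percent GC and percent CpG dinucleotides in a window of +/- halfwidth
    bases around ``pos`` (151 bases at the default), truncated at chromosome
    edges.  N bases are excluded from both numerator and denominator; the
    CpG denominator is the number of possible dinucleotide starts (L - 1).
    """
    seq = reference[chrom]
    length = len(seq)
    if not (1 <= pos <= length):
        raise ValueError(f"position {chrom}:{pos} outside chromosome (1..{length})")
    lo = max(1, pos - halfwidth)
    hi = min(length, pos + halfwidth)
    window = seq[lo - 1 : hi].upper()
    n_valid = sum(1 for b in window if b != "N")
    if n_valid == 0:
        return float("nan"), float("nan")
    gc = 100.0 * sum(1 for b in window if b in "GC") / n_valid
    if n_valid < 2:
        return gc, float("nan")
    cpg = 100.0 * window.count("CG") / (n_valid - 1)
    return gc, cpg


class GeneFeatureTable:
    """Gene-level (category C) feature table with median imputation.

    Column medians are computed once over the supplied protein-coding gene
    universe and substituted for absent genes or missing values.
    """

    def __init__(self, frame: pd.DataFrame):
        missing = set(CATEGORY_FEATURES["C"]) - set(frame.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        self.frame = frame
        self.medians = frame[CATEGORY_FEATURES["C"]].median()

    def value(self, gene_id: str, feature: str) -> float:
        if gene_id in self.frame.index:
            v = self.frame.at[gene_id, feature]
            if pd.notna(v):
                return float(v)
        return float(self.medians[feature])


@dataclass
class FeatureVector:
    """Named feature values with a per-feature missingness mask."""

    values: pd.Series
    missing_mask: pd.Series

    def validate(self) -> None:
        flags = [f for f in REGION_FLAGS.values() if f in self.values.index]
        if flags and not np.isclose(self.values[flags].sum(), 1.0):
            raise ValueError("region one-hot flags must sum to 1")


def assemble(
    av: AnnotatedVariant,
    config: str,
    panel: Optional[PopulationPanel] = None,
    tracks: Optional[Mapping[str, FeatureTrack]] = None,
    gene_table: Optional[GeneFeatureTable] = None,
    reference: Optional[Mapping[str, str]] = None,
) -> FeatureVector:
    """Populate the features of the requested categories for one variant.

    Category C values are joined by gene id with gene-universe medians
    substituted for absent genes; category D one-hot flags come from the
    resolved region; missing position/window features are flagged in the
    mask and left NaN for later training-median imputation.
    """
    if not av.is_retained or av.gene_id is None:
        raise ValueError(f"{av.key}: not a retained, gene-associated variant")
    names = feature_names(config)
    values: Dict[str, float] = {}
    mask: Dict[str, bool] = {}
    v = av.variant
    gc = cpg = None
    for name in names:
        if name in TRACK_FEATURES:
            if tracks is None or name not in tracks:
                raise ValueError(f"no track supplied for feature {name!r}")
            x = tracks[name].lookup(v.chrom, v.pos)
        elif name in WINDOW_AF_FEATURES:
            if panel is None:
                raise ValueError(f"feature {name!r} requires a population panel")
            stat, pop = WINDOW_AF_FEATURES[name]
            x = window_af_stat(v, panel, stat, pop)
        elif name in CATEGORY_FEATURES["C"]:
            if gene_table is None:
                raise ValueError("category C requires a gene feature table")
            x = gene_table.value(av.gene_id, name)
        elif name in ("GC", "CpG"):
            if reference is None:
                raise ValueError("category D requires a reference sequence")
            if gc is None:
                gc, cpg = gc_cpg_content(v.chrom, v.pos, reference)
            x = gc if name == "GC" else cpg
        elif name in REGION_FLAGS.values():
            x = 1.0 if REGION_FLAGS[av.region] == name else 0.0
        else:  # pragma: no cover - schema exhaustive
            raise KeyError(name)
        values[name] = x
        mask[name] = bool(np.isnan(x))
    fv = FeatureVector(
        pd.Series(values, index=names, dtype=float),
        pd.Series(mask, index=names, dtype=bool),
    )
    if "D" in config.upper():
        fv.validate()
    return fv


def assemble_matrix(
    avs: Sequence[AnnotatedVariant],
    config: str,
    panel: Optional[PopulationPanel] = None,
    tracks: Optional[Mapping[str, FeatureTrack]] = None,
    gene_table: Optional[GeneFeatureTable] = None,
    reference: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Feature matrix for a batch of variants (rows indexed by variant key;
    missing entries are NaN)."""
    names = feature_names(config)
    rows = np.empty((len(avs), len(names)), dtype=float)
    for i, av in enumerate(avs):
        rows[i] = assemble(av, config, panel, tracks, gene_table, reference).values.to_numpy()
    return pd.DataFrame(rows, index=[av.key for av in avs], columns=names)


def training_medians(matrix: pd.DataFrame) -> pd.Series:
    """Per-feature medians from training rows; errors on all-missing
    features so silent zero-information columns cannot slip through."""
    all_missing = matrix.columns[matrix.isna().all()]
    if len(all_missing):
        raise ValueError(
            f"features entirely missing in training rows: {list(all_missing)}"
        )
    return matrix.median()


def impute(matrix: pd.DataFrame, medians: pd.Series) -> pd.DataFrame:
    """Replace masked (NaN) entries by the supplied training medians.

    The medians must come from training rows only so the training/test
    separation is preserved.
    """
    return matrix.fillna(medians)
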