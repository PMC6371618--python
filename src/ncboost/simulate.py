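"""Self-contained synthetic study inputs with controllable planted signal.

The generator emits a small random genome, gene models (multi-exon
protein-coding genes plus non-coding RNAs, including engineered overlap and
equidistance cases), a population allele-frequency panel, position-indexed
feature tracks, a gene-level constraint table and a labeled positive cohort
whose region composition follows the curated pathogenic set: intronic 23%,
5'UTR 36%, 3'UTR 12%, upstream 26%, with downstream and intergenic variants
as the remaining minority.

Planted signal is an additive location shift (in SD units of each track's
baseline) applied at the positive variants' positions, with per-feature
orientation so that "more pathogenic" always means "more constrained".
Setting every effect size to zero yields an exchangeable null.  The
generator makes no attempt at population-genetic realism (no linkage, no
coalescent history): it exists to exercise the machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .annotate import GeneIndex, annotate_variant
from .features import (
    CATEGORY_FEATURES,
    FeatureTrack,
    GeneFeatureTable,
    POPULATIONS,
    PopulationPanel,
)
from .types import (
    NONCODING_RNA,
    PROTEIN_CODING,
    AnnotatedVariant,
    GeneModel,
    Transcript,
    VariantRecord,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

DEFAULT_REGION_MIXTURE = {
    "intronic": 0.23,
    "UTR5": 0.36,
    "UTR3": 0.12,
    "upstream": 0.26,
    "downstream": 0.01,
    "intergenic": 0.01,
}

SOURCES = ("HGMD", "CV", "SM")


@dataclass
class FixtureSpec:
    """Parameters of a synthetic study fixture.

    The defaults are sized so that a k=10 gene partition leaves at least one
    positive outside every model's excluded partition and so that matched
    1:10 negative sampling (one negative gene per negative, drawn within the
    positive's partition and region) always has sufficient pool depth.
    """

    n_chrom: int = 2
    chrom_lengths: Tuple[int, ...] = (1_000_000, 1_000_000)
    gc_fraction: float = 0.41
    n_genes: int = 360  # protein-coding genes
    ncrna_fraction: float = 0.10  # non-coding RNA genes, as a fraction of n_genes
    panel_density: float = 20.0  # panel variants per kb
    af_shape: Tuple[float, float] = (0.5, 0.5)  # Beta parameters of the AF spectrum
    effect_sizes: Dict[str, float] = field(
        default_factory=lambda: {"A": 2.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0}
    )
    region_mixture: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_MIXTURE)
    )
    n_pos: int = 30
    neg_ratio: int = 10
    seed: int = 0

    def normalized_mixture(self) -> Dict[str, float]:
        total = sum(self.region_mixture.values())
        return {r: f / total for r, f in self.region_mixture.items()}


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def make_reference(spec: FixtureSpec) -> Dict[str, str]:
    """Random nucleotide sequences with the requested GC fraction."""
    for L in spec.chrom_lengths[: spec.n_chrom]:
        if L < 10_000:
            raise ValueError("chromosome lengths must be >= 10 kb")
    rng = _rng(spec, 1)
    gc = spec.gc_fraction
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = {}
    for i in range(spec.n_chrom):
        L = spec.chrom_lengths[i]
        idx = rng.choice(4, size=L, p=p)
        out[f"chr{i + 1}"] = _BASES[idx].tobytes().decode()
    return out


def _build_coding_gene(
    gene_id: str, symbol: str, chrom: str, anchor: int, strand: str, rng
) -> GeneModel:
    """Three-exon protein-coding gene with UTR5/CDS/UTR3 structure laid out
    left-to-right; on the minus strand the left terminal block is the 3'UTR."""
    left_utr = int(rng.integers(150, 301)) if strand == "+" else int(rng.integers(150, 401))
    right_utr = int(rng.integers(150, 401)) if strand == "+" else int(rng.integers(150, 301))
    cds = [int(rng.integers(120, 301)) for _ in range(3)]
    introns = [int(rng.integers(200, 601)) for _ in range(2)]
    e1 = (anchor, anchor + left_utr + cds[0] - 1)
    i1s = e1[1] + 1
    e2 = (i1s + introns[0], i1s + introns[0] + cds[1] - 1)
    i2s = e2[1] + 1
    e3 = (i2s + introns[1], i2s + introns[1] + cds[2] + right_utr - 1)
    cds_start = anchor + left_utr
    cds_end = e3[1] - right_utr
    tx = Transcript(
        tx_id=f"{gene_id}.t1",
        tx_start=e1[0],
        tx_end=e3[1],
        exons=(e1, e2, e3),
        cds_start=cds_start,
        cds_end=cds_end,
    )
    return GeneModel(gene_id, symbol, chrom, strand, PROTEIN_CODING, (tx,))


def make_gene_models(spec: FixtureSpec, reference: Mapping[str, str]) -> List[GeneModel]:
    """Sequentially packed gene models with engineered corner cases.

    Includes one exactly equidistant gene pair (to realize ``conflicting``
    annotations at the midpoint of their gap) and non-coding RNAs both
    embedded inside coding introns (to exercise the ncRNA precedence tier)
    and standing alone between genes.
    """
    rng = _rng(spec, 2)
    chroms = sorted(reference)
    per_chrom = [spec.n_genes // spec.n_chrom] * spec.n_chrom
    for i in range(spec.n_genes % spec.n_chrom):
        per_chrom[i] += 1
    margin = 3000
    genes: List[GeneModel] = []
    gaps: Dict[str, List[Tuple[int, int]]] = {c: [] for c in chroms}
    for ci, chrom in enumerate(chroms):
        L = len(reference[chrom])
        cursor = margin
        prev_end = None
        for j in range(per_chrom[ci]):
            if ci == 0 and j == 1:
                # engineered equidistant pair: hull gap of exactly 3000 bp so
                # the midpoint is an integer position equidistant to both
                anchor = prev_end + 3000
            else:
                anchor = cursor + int(rng.integers(0, 120))
            strand = "+" if rng.random() < 0.5 else "-"
            g = _build_coding_gene(
                f"gene_{chrom}_{j:03d}", f"G{ci + 1}_{j:03d}", chrom, anchor, strand, rng
            )
            if g.end > L - margin:
                raise ValueError(
                    f"infeasible packing: gene {g.gene_id} exceeds {chrom} bounds"
                )
            if prev_end is not None:
                gaps[chrom].append((prev_end, anchor))
            genes.append(g)
            prev_end = g.end
            cursor = g.end + int(rng.integers(2600, 3201))

    coding = [g for g in genes if g.is_coding]
    n_nc = int(round(spec.n_genes * spec.ncrna_fraction))
    n_embedded = n_nc // 2
    hosts = list(rng.choice(len(coding), size=min(n_embedded, len(coding)), replace=False))
    nc: List[GeneModel] = []
    for t, hi in enumerate(hosts):
        host = coding[int(hi)]
        tx = host.transcripts[0]
        i1s, i1e = tx.exons[0][1] + 1, tx.exons[1][0] - 1
        s = i1s + 20
        e = min(s + int(rng.integers(60, 141)), i1e - 20)
        if e - s < 30:
            continue
        ntx = Transcript(tx_id=f"nc_emb_{t}.t1", tx_start=s, tx_end=e, exons=((s, e),))
        nc.append(
            GeneModel(
                f"ncg_emb_{t:03d}", f"NCE{t:03d}", host.chrom,
                "+" if rng.random() < 0.5 else "-", NONCODING_RNA, (ntx,),
            )
        )
    # standalone two-exon ncRNAs centred in inter-gene gaps (skipping the
    # engineered equidistant-pair gap, which must stay empty)
    t = 0
    for chrom in chroms:
        usable = [
            (a, b)
            for gi, (a, b) in enumerate(gaps[chrom])
            if not (chrom == chroms[0] and gi == 0) and b - a > 2400
        ]
        take = min(len(usable), (n_nc - n_embedded + len(chroms) - 1) // len(chroms))
        if take <= 0:
            continue
        for a, b in [usable[int(i)] for i in rng.choice(len(usable), size=take, replace=False)]:
            span = 100 + 150 + 100
            s = a + (b - a - span) // 2
            e1 = (s, s + 99)
            e2 = (s + 250, s + 349)
            ntx = Transcript(
                tx_id=f"nc_sa_{t}.t1", tx_start=e1[0], tx_end=e2[1], exons=(e1, e2)
            )
            nc.append(
                GeneModel(
                    f"ncg_sa_{t:03d}", f"NCS{t:03d}", chrom,
                    "+" if rng.random() < 0.5 else "-", NONCODING_RNA, (ntx,),
                )
            )
            t += 1
    all_genes = genes + nc
    for g in all_genes:
        g.validate()
    return all_genes


def make_population_panel(spec: FixtureSpec, reference: Mapping[str, str]) -> PopulationPanel:
    """Poisson-density panel with a Beta allele-frequency spectrum folded to
    MAF, jittered per-population frequencies, derived allele frequencies and
    a COMMON flag consistent with the MAF thresholds."""
    rng = _rng(spec, 3)
    a, b = spec.af_shape
    frames = []
    for chrom in sorted(reference):
        L = len(reference[chrom])
        n = int(rng.poisson(L / 1000.0 * spec.panel_density))
        pos = np.sort(rng.choice(L, size=min(n, L), replace=False)) + 1
        af = rng.beta(a, b, size=len(pos))
        maf = np.minimum(af, 1.0 - af)
        seq = reference[chrom]
        ref_idx = np.array(["ACGT".index(seq[p - 1]) for p in pos])
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        data = {
            "chrom": chrom,
            "pos": pos,
            "id": [f"rs_{chrom}_{p}" for p in pos],
            "ref": [chr(_BASES[i][0]) for i in ref_idx],
            "alt": [chr(_BASES[i][0]) for i in alt_idx],
            "maf": maf,
            "daf": af,
            "common": maf > 0.05,
        }
        for p in POPULATIONS:
            if p == "global":
                continue
            jitter = np.exp(rng.normal(0.0, 0.2, size=len(pos)))
            x = np.clip(maf * jitter, 0.0, 1.0)
            data[f"maf_{p}"] = np.minimum(x, 1.0 - x)
        frames.append(pd.DataFrame(data))
    return PopulationPanel(pd.concat(frames, ignore_index=True))


def panel_variant_records(panel: PopulationPanel) -> List[VariantRecord]:
    """Panel rows as VariantRecord objects (for annotation / classification)."""
    pops = [p for p in POPULATIONS if p != "global"]
    out = []
    for row in panel.frame.itertuples(index=False):
        out.append(
            VariantRecord(
                chrom=row.chrom,
                pos=int(row.pos),
                ref=row.ref,
                alt=row.alt,
                id=row.id,
                maf=float(row.maf),
                maf_by_pop={p: float(getattr(row, f"maf_{p}")) for p in pops},
                daf=float(row.daf),
                common_flag=bool(row.common),
                source="panel",
            )
        )
    return out


@dataclass(frozen=True)
class TrackDef:
    name: str
    category: str
    bin_size: int
    sampler: Callable[[np.random.Generator, int], np.ndarray]
    orientation: int  # +1: pathogenic shifts up; -1: down; 0: never planted
    bounds: Optional[Tuple[float, float]] = None
    gap_fraction: float = 0.0


def _track_defs() -> List[TrackDef]:
    defs: List[TrackDef] = [
        TrackDef("GerpN", "A", 100, lambda r, n: r.normal(2, 1, n), +1, None, 0.01),
        TrackDef("GerpS", "A", 100, lambda r, n: r.normal(0, 1.5, n), +1, None, 0.01),
        TrackDef("priPhCons", "A", 100, lambda r, n: r.beta(0.3, 1.5, n), +1, (0, 1), 0.01),
        TrackDef("mamPhCons", "A", 100, lambda r, n: r.beta(0.3, 1.5, n), +1, (0, 1), 0.01),
        TrackDef("verPhCons", "A", 100, lambda r, n: r.beta(0.3, 1.5, n), +1, (0, 1), 0.01),
        TrackDef("priPhyloP", "A", 100, lambda r, n: r.normal(0.5, 1, n), +1, None, 0.01),
        TrackDef("mamPhyloP", "A", 100, lambda r, n: r.normal(0, 1, n), +1, None, 0.01),
        TrackDef("verPhyloP", "A", 100, lambda r, n: r.normal(0, 1, n), +1, None, 0.01),
        TrackDef("bStatistic", "B", 1000, lambda r, n: r.beta(5, 2, n), -1, (0, 1)),
        TrackDef("CDTS", "B", 10, lambda r, n: r.normal(0, 1, n), -1, None),
    ]
    for test in ("TajimasD", "FuLisD", "FuLisF"):
        for pop in ("CEU", "CHB", "YRI"):
            defs.append(
                TrackDef(
                    f"{test}_{pop}_pvalue",
                    "B",
                    5000,
                    lambda r, n: np.minimum(-np.log10(r.uniform(1e-7, 1, n)), 6.0),
                    +1,
                    (0, 6),
                )
            )
    e_specs = {
        "EncOCDNaseSig": lambda r, n: r.exponential(1.0, n),
        "EncOCDNasePVal": lambda r, n: r.exponential(2.0, n),
        "EncOCFaireSig": lambda r, n: r.exponential(1.0, n),
        "EncOCFairePVal": lambda r, n: r.exponential(2.0, n),
        "EncOCctcfSig": lambda r, n: r.exponential(1.0, n),
        "EncOCctcfPVal": lambda r, n: r.exponential(2.0, n),
        "EncOCpolIISig": lambda r, n: r.exponential(1.0, n),
        "EncOCpolIIPVal": lambda r, n: r.exponential(2.0, n),
        "EncOCmycSig": lambda r, n: r.exponential(1.0, n),
        "EncOCmycPVal": lambda r, n: r.exponential(2.0, n),
        "EncOCCombPVal": lambda r, n: r.exponential(2.0, n),
        "EncOCC": lambda r, n: r.integers(0, 11, n).astype(float),
        "EncNucleo": lambda r, n: r.exponential(1.0, n),
        "TFBS": lambda r, n: r.poisson(2.0, n).astype(float),
        "TFBSPeaks": lambda r, n: r.poisson(5.0, n).astype(float),
        "TFBSPeaksMax": lambda r, n: r.exponential(100.0, n),
        "EncH3K4Me1": lambda r, n: r.exponential(5.0, n),
        "EncH3K4Me3": lambda r, n: r.exponential(5.0, n),
        "EncH3K27Ac": lambda r, n: r.exponential(5.0, n),
    }
    for name, sampler in e_specs.items():
        defs.append(TrackDef(name, "E", 200, sampler, +1))
    return defs


#: Gene-level feature generators: (sampler, orientation, bounds).
_GENE_FEATURE_DEFS: Dict[str, Tuple[Callable, int, Optional[Tuple[float, float]]]] = {
    "ncRVIS": (lambda r, n: r.normal(0, 1, n), -1, None),
    "ncGERP": (lambda r, n: r.normal(2, 1, n), +1, None),
    "dNdS": (lambda r, n: r.lognormal(-1.5, 0.5, n), -1, (0, None)),
    "pLI": (lambda r, n: r.beta(0.5, 0.5, n), +1, (0, 1)),
    "RVIS_percentile": (lambda r, n: r.uniform(0, 100, n), -1, (0, 100)),
    "GDI": (lambda r, n: r.lognormal(1.0, 0.5, n), -1, (0, None)),
    "familyMemberCount": (lambda r, n: r.poisson(3.0, n).astype(float), 0, (0, None)),
    "gene_age": (lambda r, n: r.integers(0, 13, n).astype(float), -1, (0, 12)),
}


def _make_tracks(
    spec: FixtureSpec, reference: Mapping[str, str], rng: np.random.Generator
) -> Dict[str, FeatureTrack]:
    tracks: Dict[str, FeatureTrack] = {}
    for td in _track_defs():
        data = {}
        for chrom in sorted(reference):
            L = len(reference[chrom])
            starts = np.arange(1, L + 1, td.bin_size, dtype=np.int64)
            ends = np.minimum(starts + td.bin_size - 1, L)
            values = td.sampler(rng, len(starts))
            if td.bounds is not None:
                lo, hi = td.bounds
                values = np.clip(values, lo, hi if hi is not None else np.inf)
            if td.gap_fraction > 0:
                keep = rng.random(len(starts)) >= td.gap_fraction
                starts, ends, values = starts[keep], ends[keep], values[keep]
            data[chrom] = (starts, ends, values)
        tracks[td.name] = FeatureTrack(td.name, data, resolution=td.bin_size)
    return tracks


def _allocate_counts(n: int, mixture: Mapping[str, float]) -> Dict[str, int]:
    """Largest-remainder allocation of n positives to region classes."""
    items = sorted(mixture.items())
    raw = {r: n * f for r, f in items}
    counts = {r: int(np.floor(x)) for r, x in raw.items()}
    short = n - sum(counts.values())
    for r, _ in sorted(items, key=lambda kv: -(raw[kv[0]] - counts[kv[0]]))[:short]:
        counts[r] += 1
    return counts


def _candidate_position(
    gene: GeneModel, region: str, rng: np.random.Generator
) -> Optional[int]:
    tx = gene.transcripts[0]
    s = gene.strand
    if region == "intronic":
        i = int(rng.integers(2))
        lo, hi = tx.exons[i][1] + 11, tx.exons[i + 1][0] - 11
    elif region == "UTR5":
        lo, hi = (tx.tx_start, tx.cds_start - 1) if s == "+" else (tx.cds_end + 1, tx.tx_end)
    elif region == "UTR3":
        lo, hi = (tx.cds_end + 1, tx.tx_end) if s == "+" else (tx.tx_start, tx.cds_start - 1)
    elif region == "upstream":
        lo, hi = (gene.start - 1000, gene.start - 1) if s == "+" else (gene.end + 1, gene.end + 1000)
    elif region == "downstream":
        lo, hi = (gene.end + 1, gene.end + 1000) if s == "+" else (gene.start - 1000, gene.start - 1)
    elif region == "intergenic":
        side = int(rng.integers(2))
        if side == 0:
            lo, hi = gene.end + 1001, gene.end + 1400
        else:
            lo, hi = gene.start - 1400, gene.start - 1001
    else:  # pragma: no cover
        raise KeyError(region)
    if hi < lo:
        return None
    return int(rng.integers(lo, hi + 1))


def make_feature_tracks_and_cohort(
    spec: FixtureSpec,
    genes: Sequence[GeneModel],
    panel: PopulationPanel,
    reference: Mapping[str, str],
) -> Tuple[Dict[str, FeatureTrack], GeneFeatureTable, List[AnnotatedVariant]]:
    """Generate feature tracks and the labeled positive cohort.

    Positives are placed per the region mixture in non-coding regions of
    distinct protein-coding genes (each placement verified by re-annotation
    against the full gene index), then the requested per-category effect
    sizes are planted at their positions in the tracks and, for category C,
    in the gene-level table.
    """
    rng_tracks = _rng(spec, 4)
    rng = _rng(spec, 5)
    tracks = _make_tracks(spec, reference, rng_tracks)
    index = GeneIndex(genes)
    coding = sorted((g for g in genes if g.is_coding), key=lambda g: g.gene_id)

    counts = _allocate_counts(spec.n_pos, spec.normalized_mixture())
    if sum(counts.values()) != spec.n_pos:
        raise AssertionError("region allocation does not sum to n_pos")
    panel_positions = {
        (row.chrom, int(row.pos)) for row in panel.frame.itertuples(index=False)
    }

    order = [coding[int(i)] for i in rng.permutation(len(coding))]
    gene_iter = iter(order)
    positives: List[AnnotatedVariant] = []
    for region in sorted(counts):
        placed = 0
        while placed < counts[region]:
            try:
                gene = next(gene_iter)
            except StopIteration:
                raise ValueError(
                    f"region mixture unrealizable: could not place {counts[region] - placed}"
                    f" more positives in region {region!r}"
                )
            found = None
            for _ in range(40):
                pos = _candidate_position(gene, region, rng)
                if pos is None or (gene.chrom, pos) in panel_positions:
                    continue
                if not (1 <= pos <= len(reference[gene.chrom])):
                    continue
                ref_base = reference[gene.chrom][pos - 1]
                alt = "ACGT".replace(ref_base, "")[int(rng.integers(3))]
                srcs = {SOURCES[int(rng.choice(3, p=[0.45, 0.35, 0.2]))]}
                if rng.random() < 0.25:
                    srcs.add(SOURCES[int(rng.integers(3))])
                v = VariantRecord(
                    chrom=gene.chrom,
                    pos=pos,
                    ref=ref_base,
                    alt=alt,
                    id=f"path_{len(positives):03d}",
                    hom_carriers=0,
                    source=";".join(sorted(srcs)),
                )
                av = annotate_variant(v, index)
                if av is not None and av.region == region and av.gene_id == gene.gene_id:
                    found = av
                    break
            if found is not None:
                positives.append(found)
                placed += 1

    # plant per-category effects at the positive positions
    track_sd = {name: tr.values_std() for name, tr in tracks.items()}
    defs_by_name = {td.name: td for td in _track_defs()}
    for av in positives:
        v = av.variant
        for name, tr in tracks.items():
            td = defs_by_name[name]
            shift = spec.effect_sizes.get(td.category, 0.0)
            if shift == 0.0 or td.orientation == 0:
                continue
            base = tr.lookup(v.chrom, v.pos)
            if np.isnan(base):
                base = float(np.nanmedian(np.concatenate(
                    [vals for _, _, vals in tr._data.values()]
                )))
            value = base + td.orientation * shift * track_sd[name]
            if td.bounds is not None:
                lo, hi = td.bounds
                value = float(np.clip(value, lo, hi if hi is not None else np.inf))
            tr.plant(v.chrom, v.pos, value)

    # gene-level (category C) table over the protein-coding universe
    rng_genes = _rng(spec, 6)
    gene_ids = [g.gene_id for g in coding]
    table = {}
    for feat in CATEGORY_FEATURES["C"]:
        sampler, orient, bounds = _GENE_FEATURE_DEFS[feat]
        table[feat] = sampler(rng_genes, len(gene_ids))
    frame = pd.DataFrame(table, index=gene_ids)
    c_shift = spec.effect_sizes.get("C", 0.0)
    pos_genes = {av.gene_id for av in positives}
    if c_shift:
        for feat in CATEGORY_FEATURES["C"]:
            sampler, orient, bounds = _GENE_FEATURE_DEFS[feat]
            if orient == 0:
                continue
            sd = float(frame[feat].std())
            sel = frame.index.isin(pos_genes)
            shifted = frame.loc[sel, feat] + orient * c_shift * sd
            if bounds is not None:
                lo, hi = bounds
                shifted = shifted.clip(lower=lo, upper=hi)
            frame.loc[sel, feat] = shifted
    # sprinkle missing values outside the positive genes to exercise the
    # gene-universe median imputation
    holes = rng_genes.random(frame.shape) < 0.05
    holes[frame.index.isin(pos_genes), :] = False
    frame = frame.mask(holes)
    return tracks, GeneFeatureTable(frame), positives


@dataclass
class FixtureBundle:
    """Everything a run needs, generated deterministically from one spec."""

    spec: FixtureSpec
    reference: Dict[str, str]
    genes: List[GeneModel]
    gene_index: GeneIndex
    panel: PopulationPanel
    tracks: Dict[str, FeatureTrack]
    gene_table: GeneFeatureTable
    positives: List[AnnotatedVariant]

    @property
    def coding_gene_universe(self) -> List[Tuple[str, str]]:
        return [(g.gene_id, g.chrom) for g in self.genes if g.is_coding]


def build_fixture(spec: Optional[FixtureSpec] = None) -> FixtureBundle:
    spec = spec if spec is not None else FixtureSpec()
    reference = make_reference(spec)
    genes = make_gene_models(spec, reference)
    panel = make_population_panel(spec, reference)
    tracks, gene_table, positives = make_feature_tracks_and_cohort(
        spec, genes, panel, reference
    )
    return FixtureBundle(
        spec=spec,
        reference=reference,
        genes=genes,
        gene_index=GeneIndex(genes),
        panel=panel,
        tracks=tracks,
        gene_table=gene_table,
        positives=positives,
    )
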