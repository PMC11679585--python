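"""Seeded synthetic RRBS data: genome, digestion, truth and call tables.

The generator emulates the geometry of an RRBS experiment contrasting a
drug-sensitive line (S), its resistant derivative (R) and the resistant
line after treatment (RC), two replicates each:

* a small genome of CpG-poor background with CpG-island interspersion and
  one short chromosome made of a tandemly repeated CpG-dense unit (the
  stand-in for an rDNA-like repeat array);
* in-silico MspI digestion (C^CGG) with size selection, which defines the
  CpG universe that can appear in call tables — the defining enrichment
  step of RRBS;
* planted truth regions per class (reversion, resistance-only,
  treatment-only, null background) with per-condition methylation means;
* per-sample counts: negative-binomial coverage per strand cytosine (both
  strands of each CpG are reported, as a bisulfite caller would) and
  beta-binomial methylated counts with overdispersion rho.

One integer seed fixes the genome, the truth and all six call tables.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GenerationError, UsageError
from .io import (
    GeneModel,
    SampleTable,
    write_gene_models,
    write_meth_calls,
)

__all__ = [
    "GenomeSpec",
    "PlantConfig",
    "TruthRegion",
    "Genome",
    "build_genome",
    "msp1_digest",
    "digest_coords",
    "size_select",
    "plant_truth",
    "RrbsSimulation",
    "simulate_null_samples",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
_COND_INDEX = {"S": 0, "R": 1, "RC": 2}

# per-condition methylation means of the planted classes
CLASS_MU = {
    "reversion": (0.20, 0.80, 0.30),
    "resistance_only": (0.20, 0.80, 0.80),
    "treatment_hypo": (0.70, 0.70, 0.20),
    "treatment_hyper": (0.30, 0.30, 0.80),
}


@dataclass
class GenomeSpec:
    """Layout of the synthetic genome.

    Three autosome-like chromosomes carry CpG islands and gene models; one
    short chromosome is a tandem array of a single CpG-dense repeat unit.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 700_000, "chr2": 700_000,
                                 "chr3": 650_000}
    )
    array_chrom: str = "chrArr"
    array_length: int = 250_000
    array_unit_len: int = 2_000
    n_cgi_per_autosome: int = 30
    cgi_len_range: tuple[int, int] = (1_000, 1_800)
    genes_per_autosome: int = 20
    seed: int = 0


@dataclass
class PlantConfig:
    """How many truth regions of each class to plant, and where.

    ``region_len`` is the grid-aligned length of each autosomal planted
    region (multiples of 200 bp); with ``array_reversion`` the whole repeat
    array is planted as one reversion region, concentrating the
    treatment-demethylation signal on that chromosome.
    """

    n_reversion: int = 16
    n_treatment_hypo: int = 9
    n_treatment_hyper: int = 6
    n_resistance_only: int = 10
    array_reversion: bool = True
    region_len: int = 600
    rho: float = 0.02


@dataclass
class TruthRegion:
    """A planted interval with its per-condition methylation means."""

    chrom: str
    start: int  # 0-based half-open, aligned to the 200-bp grid
    end: int
    cls: str  # reversion / resistance_only / treatment_only / null
    mu_S: float
    mu_R: float
    mu_RC: float
    rho: float = 0.02


@dataclass
class Genome:
    """Sequences plus the annotation tracks derived while building them."""

    spec: GenomeSpec
    seqs: dict[str, np.ndarray] = field(repr=False)  # uint8 codes 0..3
    cgi: pd.DataFrame = field(repr=False)  # chrom,start,end
    ccre: pd.DataFrame = field(repr=False)  # chrom,start,end,label
    genes: list[GeneModel] = field(repr=False)
    array_interval: tuple[str, int, int] | None = None

    def sequence(self, chrom: str) -> str:
        return _BASES[self.seqs[chrom]].tobytes().decode()

    def fasta(self, path: str | Path, width: int = 60) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for chrom in self.seqs:
                fh.write(f">{chrom}\n")
                seq = self.sequence(chrom)
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")
        return path


def _background_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """CpG-depleted background: mutate most CpG guanines to A."""
    codes = rng.choice(4, size=length, p=[0.3, 0.2, 0.2, 0.3]).astype(np.uint8)
    cg = np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G))
    kill = cg[rng.random(cg.size) < 0.85] + 1
    codes[kill] = _A
    return codes


def _cgi_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    """GC- and CpG-rich island sequence (no depletion)."""
    return rng.choice(4, size=length, p=[0.2, 0.3, 0.3, 0.2]).astype(np.uint8)


def build_genome(spec: GenomeSpec) -> Genome:
    """Deterministically build the genome and its truth tracks from a seed."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    seqs: dict[str, np.ndarray] = {}
    cgi_rows, ccre_rows = [], []
    genes: list[GeneModel] = []

    for chrom, length in spec.chrom_lengths.items():
        codes = _background_seq(rng, length)
        # place non-overlapping CGIs with a generous gap
        lo, hi = spec.cgi_len_range
        placed: list[tuple[int, int]] = []
        attempts = 0
        while len(placed) < spec.n_cgi_per_autosome:
            attempts += 1
            if attempts > 10_000:
                raise GenerationError(
                    f"{chrom}: cannot place {spec.n_cgi_per_autosome} CGIs"
                )
            clen = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(2_000, length - clen - 2_000))
            if all(start >= e + 3_000 or start + clen <= s - 3_000
                   for s, e in placed):
                placed.append((start, start + clen))
        placed.sort()
        for s, e in placed:
            if not (0 <= s < e <= length):
                raise GenerationError(f"{chrom}: CGI [{s},{e}) out of bounds")
            codes[s:e] = _cgi_seq(rng, e - s)
            cgi_rows.append((chrom, s, e))
        seqs[chrom] = codes

        # gene models: most TSSs sit on a CGI (promoter CGIs)
        cgi_cycle = rng.permutation(len(placed))
        gene_types = rng.choice(
            ["protein_coding", "lncRNA", "miRNA", "pseudogene", "tRNA", "other"],
            size=spec.genes_per_autosome,
            p=[0.5, 0.2, 0.1, 0.1, 0.05, 0.05],
        )
        for gi in range(spec.genes_per_autosome):
            strand = "+" if rng.random() < 0.5 else "-"
            if gi < len(placed):
                s, e = placed[cgi_cycle[gi]]
                tss0 = int((s + e) // 2)
            else:
                tss0 = int(rng.integers(5_000, length - 12_000))
            glen = int(rng.integers(3_000, 8_000))
            if strand == "+":
                gs, ge = tss0, min(tss0 + glen, length)
            else:
                gs, ge = max(0, tss0 + 1 - glen), tss0 + 1
            exlen = 300
            offsets = [0, (ge - gs) // 2 - exlen // 2, ge - gs - exlen]
            exons = sorted((gs + o, gs + o + exlen) for o in offsets)
            exons = [(max(gs, s0), min(ge, e0)) for s0, e0 in exons if s0 < e0]
            genes.append(
                GeneModel(
                    gene_id=f"{chrom}_g{gi:03d}",
                    gene_name=f"{chrom}_g{gi:03d}",
                    chrom=chrom,
                    strand=strand,
                    start=gs,
                    end=ge,
                    tss=gs + 1 if strand == "+" else ge,
                    exons=exons,
                    gene_type=str(gene_types[gi]),
                )
            )
            ccre_rows.append((chrom, max(0, tss0 - 200), tss0 + 200, "PLS"))
        # enhancer-like elements on CGIs without a promoter
        for idx in cgi_cycle[spec.genes_per_autosome:]:
            s, e = placed[idx]
            mid = (s + e) // 2
            ccre_rows.append((chrom, mid - 150, mid + 150, "ELS"))

    array_interval = None
    if spec.array_chrom and spec.array_length > 0:
        unit = _cgi_seq(
            np.random.default_rng(np.random.SeedSequence([spec.seed, 1])),
            spec.array_unit_len,
        )
        copies = spec.array_length // spec.array_unit_len
        if copies < 1:
            raise GenerationError("array chromosome shorter than one unit")
        codes = np.tile(unit, copies)
        rest = spec.array_length - copies * spec.array_unit_len
        if rest:
            codes = np.concatenate([codes, _background_seq(rng, rest)])
        seqs[spec.array_chrom] = codes
        array_interval = (spec.array_chrom, 0, copies * spec.array_unit_len)
        cgi_rows.append((spec.array_chrom, 0, copies * spec.array_unit_len))
        for u in range(0, copies, 25):  # sparse rRNA-like gene models
            gs = u * spec.array_unit_len
            genes.append(
                GeneModel(
                    gene_id=f"{spec.array_chrom}_rna{u:03d}",
                    gene_name=f"{spec.array_chrom}_rna{u:03d}",
                    chrom=spec.array_chrom,
                    strand="+",
                    start=gs,
                    end=gs + 1_000,
                    tss=gs + 1,
                    exons=[(gs, gs + 1_000)],
                    gene_type="rRNA",
                )
            )

    cgi = pd.DataFrame(cgi_rows, columns=["chrom", "start", "end"])
    ccre = pd.DataFrame(ccre_rows, columns=["chrom", "start", "end", "label"])
    ccre = ccre.sort_values(["chrom", "start"], kind="mergesort").reset_index(
        drop=True
    )
    return Genome(spec=spec, seqs=seqs, cgi=cgi, ccre=ccre, genes=genes,
                  array_interval=array_interval)


def msp1_digest(sequence: str) -> list[str]:
    """Cut a sequence at every MspI site (C^CGG).

    The cut falls between the first C and CGG of each CCGG occurrence;
    the concatenation of the returned fragments equals the input.
    """
    cuts = [m.start() + 1 for m in re.finditer("CCGG", sequence)]
    bounds = [0] + cuts + [len(sequence)]
    return [sequence[a:b] for a, b in zip(bounds, bounds[1:]) if b > a]


def digest_coords(codes: np.ndarray) -> np.ndarray:
    """MspI fragment boundaries of an encoded sequence.

    Returns an (n_fragments, 2) array of 0-based half-open intervals whose
    concatenation tiles the chromosome.
    """
    if len(codes) < 4:
        return np.array([[0, len(codes)]]) if len(codes) else np.empty((0, 2), int)
    hit = (
        (codes[:-3] == _C)
        & (codes[1:-2] == _C)
        & (codes[2:-1] == _G)
        & (codes[3:] == _G)
    )
    cuts = np.flatnonzero(hit) + 1
    bounds = np.concatenate([[0], cuts, [len(codes)]])
    return np.column_stack([bounds[:-1], bounds[1:]])


def size_select(
    fragments: np.ndarray, min_len: int = 40, max_len: int = 220
) -> np.ndarray:
    """Retain fragments with min_len <= length <= max_len.

    The retained fragments define which CpGs can appear in call tables —
    the size-selection step of RRBS library preparation.
    """
    if len(fragments) == 0:
        return fragments
    lengths = fragments[:, 1] - fragments[:, 0]
    return fragments[(lengths >= min_len) & (lengths <= max_len)]


def _cpg_positions(codes: np.ndarray) -> np.ndarray:
    """0-based positions of the C of every CpG dinucleotide."""
    if len(codes) < 2:
        return np.empty(0, dtype=np.int64)
    return np.flatnonzero((codes[:-1] == _C) & (codes[1:] == _G)).astype(np.int64)


def plant_truth(
    genome: Genome, plant: PlantConfig, seed: int
) -> list[TruthRegion]:
    """Place truth regions of each class on CGIs (and the repeat array).

    Autosomal regions are grid-aligned 600-bp (default) intervals inside
    CpG islands, one region per island; with ``array_reversion`` the whole
    repeat array is a single reversion region, so treatment demethylation
    concentrates on that chromosome.  Planted intervals are disjoint.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    if plant.region_len % 200 != 0 or plant.region_len <= 0:
        raise GenerationError("region_len must be a positive multiple of 200")
    auto_cgi = genome.cgi[
        genome.cgi["chrom"] != genome.spec.array_chrom
    ].reset_index(drop=True)
    eligible = []
    for row in auto_cgi.itertuples(index=False):
        a = -(-row.start // 200) * 200  # ceil to grid
        b = (row.end // 200) * 200
        if b - a >= plant.region_len:
            eligible.append((row.chrom, a))
    order = rng.permutation(len(eligible))
    need = (
        plant.n_reversion
        + plant.n_treatment_hypo
        + plant.n_treatment_hyper
        + plant.n_resistance_only
    )
    if need > len(eligible):
        raise GenerationError(
            f"need {need} plantable CGIs, only {len(eligible)} eligible"
        )
    classes = (
        ["reversion"] * plant.n_reversion
        + ["treatment_hypo"] * plant.n_treatment_hypo
        + ["treatment_hyper"] * plant.n_treatment_hyper
        + ["resistance_only"] * plant.n_resistance_only
    )
    regions: list[TruthRegion] = []
    for cls, idx in zip(classes, order):
        chrom, a = eligible[idx]
        mu = CLASS_MU[cls]
        stored_cls = (
            "treatment_only" if cls.startswith("treatment_") else cls
        )
        regions.append(
            TruthRegion(chrom, a, a + plant.region_len, stored_cls,
                        mu[0], mu[1], mu[2], plant.rho)
        )
    if plant.array_reversion and genome.array_interval is not None:
        chrom, a, b = genome.array_interval
        mu = CLASS_MU["reversion"]
        regions.append(
            TruthRegion(chrom, a, (b // 200) * 200, "reversion",
                        mu[0], mu[1], mu[2], plant.rho)
        )
    for r in regions:
        if r.end > len(genome.seqs[r.chrom]):
            raise GenerationError(f"planted region out of bounds: {r}")
    regions.sort(key=lambda r: (r.chrom, r.start))
    for r1, r2 in zip(regions, regions[1:]):
        if r1.chrom == r2.chrom and r2.start < r1.end:
            raise GenerationError("planted regions overlap")
    return regions


class RrbsSimulation:
    """A fully seeded synthetic RRBS experiment.

    Combines the genome, the size-selected CpG universe and the planted
    truth; produces the six condition/replicate call tables and writes a
    complete dataset directory.
    """

    def __init__(
        self,
        spec: GenomeSpec | None = None,
        plant: PlantConfig | None = None,
        seed: int = 0,
        mean_cov: float = 23.0,
        nb_size: float = 20.0,
        size_range: tuple[int, int] = (40, 220),
    ) -> None:
        from dataclasses import replace

        self.spec = replace(spec, seed=seed) if spec else GenomeSpec(seed=seed)
        self.plant_config = plant or PlantConfig()
        self.seed = seed
        self.mean_cov = mean_cov
        self.nb_size = nb_size
        self.size_range = size_range
        self.genome = build_genome(self.spec)
        self.truth = plant_truth(self.genome, self.plant_config, seed)
        self.universe = self._build_universe()

    # -- universe ---------------------------------------------------------

    def _build_universe(self) -> pd.DataFrame:
        rows = []
        for chrom, codes in self.genome.seqs.items():
            frags = size_select(digest_coords(codes), *self.size_range)
            cpgs = _cpg_positions(codes)
            if len(frags) == 0 or len(cpgs) == 0:
                continue
            j = np.searchsorted(frags[:, 0], cpgs, side="right") - 1
            ok = (j >= 0) & (cpgs + 2 <= frags[np.clip(j, 0, None), 1])
            kept = cpgs[ok]
            rows.append(pd.DataFrame({"chrom": chrom, "pos0": kept}))
        if not rows:
            raise GenerationError("no CpGs in retained fragments")
        uni = pd.concat(rows, ignore_index=True)
        uni = uni.sort_values(["chrom", "pos0"], kind="mergesort").reset_index(
            drop=True
        )
        # background means: bimodal mixture (low mode ~0.05, high ~0.9)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 3]))
        n = len(uni)
        comp = rng.choice(3, size=n, p=[0.35, 0.5, 0.15])
        mu = np.empty(n)
        mu[comp == 0] = rng.beta(1.0, 19.0, size=(comp == 0).sum())
        mu[comp == 1] = rng.beta(18.0, 2.0, size=(comp == 1).sum())
        mu[comp == 2] = rng.uniform(0.2, 0.8, size=(comp == 2).sum())
        for cond in ("S", "R", "RC"):
            uni[f"mu_{cond}"] = mu
        uni["rho"] = self.plant_config.rho
        uni["cls"] = "null"
        for r in self.truth:
            m = (
                (uni["chrom"].values == r.chrom)
                & (uni["pos0"].values >= r.start)
                & (uni["pos0"].values + 2 <= r.end)
            )
            uni.loc[m, ["mu_S", "mu_R", "mu_RC"]] = (r.mu_S, r.mu_R, r.mu_RC)
            uni.loc[m, "rho"] = r.rho
            uni.loc[m, "cls"] = r.cls
        return uni

    # -- sampling ---------------------------------------------------------

    def simulate_sample(self, condition: str, replicate: int) -> SampleTable:
        """Draw one sample's call table (deterministic per seed/sample)."""
        if condition not in _COND_INDEX:
            raise UsageError(f"condition must be S, R or RC, got {condition!r}")
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [self.seed, 10 + _COND_INDEX[condition], replicate]
            )
        )
        uni = self.universe
        n = len(uni)
        mu = uni[f"mu_{condition}"].to_numpy()
        rho = uni["rho"].to_numpy()
        p = np.where(mu < 0.5, np.clip(mu, 1e-9, None),
                     np.clip(mu, None, 1 - 1e-9))
        conc = np.where(rho > 0, (1.0 - rho) / np.maximum(rho, 1e-12), np.inf)
        draw = rho > 0
        p_site = p.copy()
        if draw.any():
            p_site[draw] = rng.beta(p[draw] * conc[draw],
                                    (1 - p[draw]) * conc[draw])
        # exact-zero/one means stay deterministic even with rho > 0
        p_site = np.where(mu == 0.0, 0.0, np.where(mu == 1.0, 1.0, p_site))

        # mean_cov is the mean per call row (per strand cytosine)
        prob = self.nb_size / (self.nb_size + self.mean_cov)
        cov_f = rng.negative_binomial(self.nb_size, prob, size=n)
        cov_r = rng.negative_binomial(self.nb_size, prob, size=n)
        meth_f = rng.binomial(cov_f, p_site)
        meth_r = rng.binomial(cov_r, p_site)

        frames = []
        for cov, meth, offset, strand in (
            (cov_f, meth_f, 1, "F"),
            (cov_r, meth_r, 2, "R"),
        ):
            keep = cov >= 1
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": uni["chrom"].values[keep],
                        "pos": uni["pos0"].values[keep] + offset,
                        "strand": strand,
                        "coverage": cov[keep].astype(np.int64),
                        "meth_count": meth[keep].astype(np.int64),
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df["meth_pct"] = 100.0 * df["meth_count"] / df["coverage"]
        df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
            drop=True
        )
        return SampleTable(f"{condition}{replicate}", condition, replicate, df)

    def samples(self, replicates: int = 2) -> list[SampleTable]:
        return [
            self.simulate_sample(cond, rep)
            for cond in ("S", "R", "RC")
            for rep in range(1, replicates + 1)
        ]

    # -- ground truth for evaluation -------------------------------------

    def truth_windows(self, min_cpgs: int = 4, win: int = 200) -> pd.DataFrame:
        """Grid windows inside planted regions that the assay can resolve.

        A window counts as recoverable ground truth when it lies fully
        inside a planted region and contains >= min_cpgs CpGs of the
        size-selected universe (fewer can never satisfy the DMC-count
        rule, regardless of method).
        """
        uni = self.universe
        rows = []
        for r in self.truth:
            pos = uni.loc[uni["chrom"] == r.chrom, "pos0"].to_numpy()
            for w in range(r.start // win, r.end // win):
                ws, we = w * win, (w + 1) * win
                if ws < r.start or we > r.end:
                    continue
                n = int(((pos >= ws) & (pos < we)).sum())
                if n >= min_cpgs:
                    rows.append((r.chrom, ws, we, r.cls, n))
        return pd.DataFrame(
            rows, columns=["chrom", "start", "end", "cls", "n_cpgs"]
        )

    # -- dataset on disk --------------------------------------------------

    def write_dataset(self, outdir: str | Path, force: bool = False,
                      replicates: int = 2) -> dict:
        """Write genome, tracks, six call tables and a checksum manifest."""
        outdir = Path(outdir)
        if outdir.exists() and any(outdir.iterdir()) and not force:
            raise UsageError(f"{outdir} is not empty (use force=True)")
        outdir.mkdir(parents=True, exist_ok=True)

        self.genome.fasta(outdir / "genome.fa")
        _write_bed(self.genome.cgi, outdir / "cgi.bed")
        _write_bed(self.genome.ccre, outdir / "ccre.bed")
        write_gene_models(self.genome.genes, outdir / "genes.bed")
        if self.genome.array_interval is not None:
            chrom, a, b = self.genome.array_interval
            (outdir / "array.bed").write_text(f"{chrom}\t{a}\t{b}\tarray\n")
        truth_df = pd.DataFrame([asdict(r) for r in self.truth])
        truth_df.to_csv(outdir / "truth_regions.tsv", sep="\t", index=False)

        sample_entries = []
        for table in self.samples(replicates=replicates):
            fname = f"{table.sample_id}.txt"
            write_meth_calls(table, outdir / fname)
            sample_entries.append(
                {
                    "file": fname,
                    "sample_id": table.sample_id,
                    "condition": table.condition,
                    "replicate": table.replicate,
                }
            )

        files = sorted(p.name for p in outdir.iterdir() if p.is_file())
        checksums = {
            name: hashlib.sha256((outdir / name).read_bytes()).hexdigest()
            for name in files
            if name != "manifest.json"
        }
        manifest = {
            "seed": self.seed,
            "mean_cov": self.mean_cov,
            "nb_size": self.nb_size,
            "size_range": list(self.size_range),
            "spec": {
                "chrom_lengths": self.spec.chrom_lengths,
                "array_chrom": self.spec.array_chrom,
                "array_length": self.spec.array_length,
                "array_unit_len": self.spec.array_unit_len,
                "n_cgi_per_autosome": self.spec.n_cgi_per_autosome,
                "cgi_len_range": list(self.spec.cgi_len_range),
                "genes_per_autosome": self.spec.genes_per_autosome,
            },
            "plant": asdict(self.plant_config),
            "samples": sample_entries,
            "tracks": {
                "cgi": "cgi.bed",
                "ccre": "ccre.bed",
                "genes": "genes.bed",
            },
            "sha256": checksums,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest


def _write_bed(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False)


def simulate_null_samples(
    n_cpgs: int = 20_000,
    seed: int = 0,
    mean_cov: float = 23.0,
    nb_size: float = 20.0,
    rho: float = 0.02,
    n_reps: int = 2,
) -> list[SampleTable]:
    """Two groups with identical per-CpG means — a pure null experiment.

    CpG means follow the background bimodal mixture; groups are labelled
    S and R so the result plugs straight into unite/diff_test.  Used for
    false-positive calibration of the differential test.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 4]))
    comp = rng.choice(3, size=n_cpgs, p=[0.35, 0.5, 0.15])
    mu = np.empty(n_cpgs)
    mu[comp == 0] = rng.beta(1.0, 19.0, size=(comp == 0).sum())
    mu[comp == 1] = rng.beta(18.0, 2.0, size=(comp == 1).sum())
    mu[comp == 2] = rng.uniform(0.2, 0.8, size=(comp == 2).sum())
    pos0 = np.arange(n_cpgs, dtype=np.int64) * 60 + 10
    conc = (1.0 - rho) / rho if rho > 0 else np.inf

    tables = []
    for cond in ("S", "R"):
        for rep in range(1, n_reps + 1):
            srng = np.random.default_rng(
                np.random.SeedSequence(
                    [seed, 5 + _COND_INDEX[cond], rep]
                )
            )
            if rho > 0:
                p_site = srng.beta(mu * conc, (1 - mu) * conc)
            else:
                p_site = mu
            prob = nb_size / (nb_size + mean_cov)
            frames = []
            for offset, strand in ((1, "F"), (2, "R")):
                cov = srng.negative_binomial(nb_size, prob, size=n_cpgs)
                meth = srng.binomial(cov, p_site)
                keep = cov >= 1
                frames.append(
                    pd.DataFrame(
                        {
                            "chrom": "chrN",
                            "pos": pos0[keep] + offset,
                            "strand": strand,
                            "coverage": cov[keep].astype(np.int64),
                            "meth_count": meth[keep].astype(np.int64),
                        }
                    )
                )
            df = pd.concat(frames, ignore_index=True)
            df["meth_pct"] = 100.0 * df["meth_count"] / df["coverage"]
            df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(
                drop=True
            )
            tables.append(SampleTable(f"{cond}{rep}", cond, rep, df))
    return tables
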