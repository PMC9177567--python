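"""Synthetic-data generators with full planted truth.

Everything the pipeline consumes can be generated here: bacterial genomes,
genomes with planted insertions/deletions/inversions, error-bearing ONT-like
long reads, per-sample SV presence profiles, coupled community feature
matrices, and cohort bundles (abundance x SV-genotype x metabolome x
phenotype) in which selected bacteria-metabolite correlations hold only in
the SV-absent (SV0) subgroup.

Every generator is a pure function of its seed and parameters; truth records
carry both reference and query coordinates so callers can be scored exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, Read, ReadSet, GeneModel, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: default minimum flank used throughout (bp); placement keeps planted SVs
#: separated by at least twice this.
FLANK_DEFAULT = 100

SV_TYPES = ("insertion", "deletion", "inversion")


class PlacementError(RuntimeError):
    """Raised when planted SVs cannot be placed without overlap."""


# ---------------------------------------------------------------------------
# genomes


def simulate_reference_genome(
    length_bp: int,
    n_contigs: int = 1,
    gc: float = 0.45,
    seed: int = 0,
) -> GenomeAssembly:
    """Random genome with the requested GC content, split into equal contigs."""
    if length_bp <= 0 or n_contigs <= 0:
        raise ValueError("length_bp and n_contigs must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError(f"gc must lie in (0,1), got {gc}")
    if length_bp < n_contigs * 1000:
        raise ValueError("need at least 1 kb per contig")
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    base = length_bp // n_contigs
    lengths = [base] * n_contigs
    lengths[0] += length_bp - base * n_contigs
    contigs = {}
    for i, clen in enumerate(lengths, start=1):
        idx = rng.choice(4, size=clen, p=probs)
        contigs[f"contig_{i}"] = _BASES[idx].tobytes().decode()
    return GenomeAssembly(contigs=contigs, name=f"ref_seed{seed}")


def gc_fraction(genome: GenomeAssembly) -> float:
    g = sum(s.count("G") + s.count("C") for s in genome.contigs.values())
    return g / genome.total_length


# ---------------------------------------------------------------------------
# SV truth types


@dataclass
class SVSpec:
    """One planted SV with both reference and query coordinates (0-based, half-open)."""

    sv_type: str
    contig: str
    ref_start: int
    ref_end: int
    query_start: int
    query_end: int
    length_bp: int
    payload: str = ""  # inserted sequence, for insertions

    def __post_init__(self) -> None:
        if self.sv_type not in SV_TYPES:
            raise ValueError(f"unknown sv_type {self.sv_type!r}")
        if self.length_bp <= 0:
            raise ValueError("length_bp must be positive")


@dataclass
class SVLengthModel:
    """Bimodal SV length distribution: two uniform peaks plus an optional
    log-uniform long tail.

    Defaults reproduce the short (140-160 bp, mobile-element-like) and long
    (1050-1150 bp) modes of gut-microbiome SV length distributions; the
    mixture is a phenomenological stand-in, not a mechanistic claim.
    """

    short_range: tuple[int, int] = (140, 160)
    long_range: tuple[int, int] = (1050, 1150)
    weight_short: float = 0.5
    weight_tail: float = 0.0
    max_len: int = 10_000
    min_sv_len: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_short <= 1.0:
            raise ValueError("weight_short must be in [0,1]")
        if not 0.0 <= self.weight_tail <= 1.0 - self.weight_short:
            raise ValueError("weight_tail must fit in the remaining mass")

    def sample(self, n: int, rng: np.random.Generator, component: str | None = None) -> np.ndarray:
        """Sample n lengths; ``component`` forces 'short'/'long'/'tail'."""
        if component is None:
            w_long = 1.0 - self.weight_short - self.weight_tail
            comps = rng.choice(
                ["short", "long", "tail"],
                size=n,
                p=[self.weight_short, w_long, self.weight_tail],
            )
        else:
            comps = np.full(n, component)
        out = np.empty(n, dtype=int)
        for i, c in enumerate(comps):
            if c == "short":
                out[i] = rng.integers(self.short_range[0], self.short_range[1] + 1)
            elif c == "long":
                out[i] = rng.integers(self.long_range[0], self.long_range[1] + 1)
            else:
                lo, hi = np.log(self.min_sv_len), np.log(self.max_len)
                out[i] = int(np.exp(rng.uniform(lo, hi)))
        return np.maximum(out, self.min_sv_len)


# ---------------------------------------------------------------------------
# planting SVs


def _random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return _BASES[rng.choice(4, size=n, p=probs)].tobytes().decode()


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def plant_svs(
    reference: GenomeAssembly,
    n_svs: int,
    type_mix: tuple[float, float, float] = (0.45, 0.45, 0.10),
    length_model: SVLengthModel | None = None,
    seed: int = 0,
    min_gap: int = 2 * FLANK_DEFAULT,
    end_buffer: int = 2 * FLANK_DEFAULT,
    max_retries: int = 1000,
    flank_k: int = 21,
) -> tuple[GenomeAssembly, list[SVSpec]]:
    """Plant non-overlapping insertions/deletions/inversions into a copy of
    ``reference``; the query genome differs from the reference exactly by the
    returned truth list.

    Inversions draw from the long length component only (large inversions are
    the class long-read assemblies resolve); inserted sequence is GC-matched
    random sequence screened against the flanks' k-mers so placement is
    unambiguous.
    """
    if n_svs < 0:
        raise ValueError("n_svs must be non-negative")
    mix = np.asarray(type_mix, dtype=float)
    if mix.min() < 0 or not np.isclose(mix.sum(), 1.0):
        raise ValueError("type_mix must be non-negative and sum to 1")
    model = length_model or SVLengthModel()
    rng = np.random.default_rng(seed)

    if n_svs == 0:
        return GenomeAssembly(dict(reference.contigs), name="query"), []

    types = [SV_TYPES[i] for i in rng.choice(3, size=n_svs, p=mix)]
    lengths = np.empty(n_svs, dtype=int)
    for i, t in enumerate(types):
        comp = "long" if t == "inversion" else None
        lengths[i] = model.sample(1, rng, component=comp)[0]
        if t == "inversion":
            lengths[i] = max(lengths[i], 50)

    contig_names = list(reference.contigs)
    clens = np.array([len(reference.contigs[c]) for c in contig_names], dtype=float)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in contig_names}
    specs: list[tuple[str, str, int, int]] = []  # (type, contig, ref_start, length)

    for i in range(n_svs):
        footprint = 0 if types[i] == "insertion" else int(lengths[i])
        ok = False
        for _ in range(max_retries):
            ci = rng.choice(len(contig_names), p=clens / clens.sum())
            contig = contig_names[ci]
            clen = int(clens[ci])
            lo, hi = end_buffer, clen - end_buffer - footprint
            if hi <= lo:
                continue
            pos = int(rng.integers(lo, hi))
            iv = (pos - min_gap, pos + footprint + min_gap)
            if all(iv[1] <= s or iv[0] >= e for s, e in placed[contig]):
                placed[contig].append((pos, pos + footprint))
                specs.append((types[i], contig, pos, int(lengths[i])))
                ok = True
                break
        if not ok:
            raise PlacementError(
                f"could not place SV {i + 1}/{n_svs} after {max_retries} retries"
            )

    specs.sort(key=lambda s: (s[1], s[2]))

    ins_gc = gc_fraction(reference)  # inserted sequence matches the genome's GC
    query_contigs: dict[str, str] = {}
    truth: list[SVSpec] = []
    for contig in contig_names:
        ref_seq = reference.contigs[contig]
        parts: list[str] = []
        cursor = 0
        q_cursor = 0
        for sv_type, c, pos, L in specs:
            if c != contig:
                continue
            parts.append(ref_seq[cursor:pos])
            q_cursor += pos - cursor
            if sv_type == "insertion":
                flanks = ref_seq[max(0, pos - FLANK_DEFAULT) : pos + FLANK_DEFAULT]
                flank_kmers = _kmers(flanks, flank_k)
                for _ in range(max_retries):
                    payload = _random_seq(L, ins_gc, rng)
                    if not (_kmers(payload, flank_k) & flank_kmers):
                        break
                parts.append(payload)
                truth.append(
                    SVSpec("insertion", contig, pos, pos, q_cursor, q_cursor + L, L, payload)
                )
                q_cursor += L
                cursor = pos
            elif sv_type == "deletion":
                truth.append(
                    SVSpec("deletion", contig, pos, pos + L, q_cursor, q_cursor, L)
                )
                cursor = pos + L
            else:  # inversion
                parts.append(reverse_complement(ref_seq[pos : pos + L]))
                truth.append(
                    SVSpec("inversion", contig, pos, pos + L, q_cursor, q_cursor + L, L)
                )
                q_cursor += L
                cursor = pos + L
        parts.append(ref_seq[cursor:])
        query_contigs[contig] = "".join(parts)

    truth.sort(key=lambda s: (s.contig, s.ref_start))
    return GenomeAssembly(query_contigs, name="query"), truth


def apply_svs(reference: GenomeAssembly, truth: list[SVSpec]) -> GenomeAssembly:
    """Re-apply a truth list to the reference (reconstruction oracle helper)."""
    out: dict[str, str] = {}
    by_contig: dict[str, list[SVSpec]] = {}
    for sv in truth:
        by_contig.setdefault(sv.contig, []).append(sv)
    for contig, seq in reference.contigs.items():
        parts: list[str] = []
        cursor = 0
        for sv in sorted(by_contig.get(contig, []), key=lambda s: s.ref_start):
            parts.append(seq[cursor : sv.ref_start])
            if sv.sv_type == "insertion":
                parts.append(sv.payload)
                cursor = sv.ref_start
            elif sv.sv_type == "deletion":
                cursor = sv.ref_end
            else:
                parts.append(reverse_complement(seq[sv.ref_start : sv.ref_end]))
                cursor = sv.ref_end
        parts.append(seq[cursor:])
        out[contig] = "".join(parts)
    return GenomeAssembly(out, name="reconstructed")


# ---------------------------------------------------------------------------
# long reads


@dataclass
class ReadParams:
    """ONT-like read model: log-normal lengths (mean 5683 bp by default),
    flat per-base error rates, linear contigs (reads truncate at ends)."""

    mean_length: float = 5683.0
    sigma_log: float = 0.55
    min_length: int = 2 * FLANK_DEFAULT
    sub_rate: float = 0.0
    ins_rate: float = 0.0
    del_rate: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.ins_rate, self.del_rate):
            if not 0.0 <= r <= 0.2:
                raise ValueError("error rates must lie in [0, 0.2]")


def _mutate(seq: str, p: ReadParams, rng: np.random.Generator) -> str:
    if p.sub_rate == p.ins_rate == p.del_rate == 0.0:
        return seq
    out = []
    bases = "ACGT"
    for ch in seq:
        u = rng.random()
        if u < p.del_rate:
            continue
        if u < p.del_rate + p.ins_rate:
            out.append(bases[rng.integers(4)])
        if rng.random() < p.sub_rate:
            alt = bases[rng.integers(4)]
            while alt == ch:
                alt = bases[rng.integers(4)]
            out.append(alt)
        else:
            out.append(ch)
    return "".join(out)


def simulate_long_reads(
    genome: GenomeAssembly,
    depth: float,
    read_params: ReadParams | None = None,
    seed: int = 0,
) -> ReadSet:
    """Sample reads to ~depth-fold coverage; each read's header records its
    true origin contig/start/strand for oracle use."""
    if depth <= 0:
        raise ValueError("depth must be positive")
    p = read_params or ReadParams()
    longest = max(len(s) for s in genome.contigs.values())
    if p.mean_length >= longest:
        raise ValueError("mean read length must be below the longest contig")
    rng = np.random.default_rng(seed)
    target = depth * genome.total_length
    n_reads = int(np.ceil(target / p.mean_length))
    mu = np.log(p.mean_length) - p.sigma_log**2 / 2
    contig_names = list(genome.contigs)
    weights = np.array([len(genome.contigs[c]) for c in contig_names], dtype=float)
    weights /= weights.sum()
    reads: list[Read] = []
    for i in range(n_reads):
        L = max(p.min_length, int(rng.lognormal(mu, p.sigma_log)))
        contig = contig_names[rng.choice(len(contig_names), p=weights)]
        clen = len(genome.contigs[contig])
        start = int(rng.integers(0, max(1, clen - p.min_length)))
        L = min(L, clen - start)  # truncate at contig end, no circularity
        seq = genome.contigs[contig][start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        seq = _mutate(seq, p, rng)
        reads.append(Read(f"read_{i:06d}", seq, contig, start, strand))
    return ReadSet(reads=reads)


# ---------------------------------------------------------------------------
# gene models / pathways


def simulate_gene_models(
    genome: GenomeAssembly,
    gene_length: int = 900,
    spacing: int = 100,
    n_pathways: int = 5,
    seed: int = 0,
) -> tuple[list[GeneModel], dict[str, str]]:
    """Tile gene models across the genome, each tagged with a distinct KO,
    and assign KOs round-robin to synthetic pathways.

    Returns (genes, ko_to_pathway).
    """
    rng = np.random.default_rng(seed)
    genes: list[GeneModel] = []
    idx = 0
    for contig, seq in genome.contigs.items():
        pos = spacing
        while pos + gene_length <= len(seq):
            idx += 1
            genes.append(
                GeneModel(
                    gene_id=f"gene_{idx:05d}",
                    contig=contig,
                    start=pos,
                    end=pos + gene_length,
                    ko=f"K{10000 + idx:05d}",
                    strand="+" if rng.random() < 0.5 else "-",
                )
            )
            pos += gene_length + spacing
    ko_to_pathway = {
        g.ko: f"path_{(i % n_pathways) + 1:03d}" for i, g in enumerate(genes)
    }
    return genes, ko_to_pathway


# ---------------------------------------------------------------------------
# SV presence profiles (fingerprint substrate)


def simulate_sv_profiles(
    n_individuals: int = 20,
    samples_per_individual: int = 1,
    n_sv_pool: int = 100,
    carriage_prob: float = 0.211,
    within_flip_prob: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Individual-specific SV presence profiles over a shared SV pool.

    Each individual draws a private profile (Bernoulli carriage per pool SV);
    repeated samples of the same individual copy it with a small flip
    probability (0 by default: within-individual stability).  With the
    default carriage 0.211 over a 100-SV pool, the expected pairwise
    inter-individual difference is 2*p*(1-p)*pool = 33.3 SVs, i.e. ~16.7 per
    Mb on a 2 Mb genome.
    """
    rng = np.random.default_rng(seed)
    rows, index, mapping = [], [], {}
    for i in range(n_individuals):
        profile = rng.random(n_sv_pool) < carriage_prob
        for t in range(samples_per_individual):
            flips = rng.random(n_sv_pool) < within_flip_prob
            sample = f"I{i + 1:02d}_t{t + 1}"
            rows.append(np.where(flips, ~profile, profile).astype(int))
            index.append(sample)
            mapping[sample] = f"I{i + 1:02d}"
    cols = [f"sv_{j + 1:03d}" for j in range(n_sv_pool)]
    return pd.DataFrame(rows, index=index, columns=cols), mapping


def simulate_coupled_presence(
    n_samples: int = 30,
    n_features: int = 120,
    flip_prob: float = 0.02,
    density: float = 0.3,
    n_groups: int = 4,
    within_group_flip: float = 0.10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two coupled binary community matrices (e.g. prophages and the CRISPR
    spacers recording them): B copies A's pattern feature-wise with a small
    flip probability, so their Jaccard-PCoA configurations co-vary.

    Samples fall into ``n_groups`` latent community types (each with its own
    base repertoire, individualised by ``within_group_flip``), the clustered
    structure real prophage/spacer repertoires show; it also gives the
    ordination dominant, stable axes."""
    rng = np.random.default_rng(seed)
    base = rng.random((n_groups, n_features)) < density
    groups = rng.integers(0, n_groups, size=n_samples)
    a = base[groups]
    a = np.where(rng.random(a.shape) < within_group_flip, ~a, a).astype(int)
    flips = rng.random((n_samples, n_features)) < flip_prob
    b = np.where(flips, 1 - a, a)
    idx = [f"S{i + 1:03d}" for i in range(n_samples)]
    fa = [f"phage_{j + 1:03d}" for j in range(n_features)]
    fb = [f"spacer_{j + 1:03d}" for j in range(n_features)]
    return (
        pd.DataFrame(a, index=idx, columns=fa),
        pd.DataFrame(b, index=idx, columns=fb),
    )


# ---------------------------------------------------------------------------
# cohort


@dataclass
class PlantedTriple:
    species: str
    ko: str
    metabolite: str
    effect_size: float  # target Spearman rho in the SV0 subgroup
    sign: int = 1


@dataclass
class CohortBundle:
    """Cohort matrices sharing one sample index, plus planted truth.

    ``sv_genotype`` columns are ``"species:KO"``; entries are NA exactly
    where the species is absent (abundance 0) in that sample.
    """

    abundance: pd.DataFrame
    sv_genotype: pd.DataFrame
    metabolites: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame
    truth: list[PlantedTriple] = field(default_factory=list)
    #: direct bacteria-metabolite correlations planted WITHOUT SV confounding
    #: (the abundant true associations any real screen family contains)
    background: list[PlantedTriple] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.abundance.index
        for m in (self.sv_genotype, self.metabolites, self.covariates):
            if not m.index.equals(idx):
                raise ValueError("all cohort matrices must share the sample index")
        if not self.phenotype.index.equals(idx):
            raise ValueError("phenotype must share the sample index")

    @property
    def samples(self) -> pd.Index:
        return self.abundance.index

    def sv_columns_for(self, species: str) -> list[str]:
        return [c for c in self.sv_genotype.columns if c.split(":", 1)[0] == species]


def simulate_cohort(
    n_samples: int = 100,
    n_species: int = 6,
    n_metabolites: int = 10,
    n_kos_per_species: int = 4,
    confounded_triples: int = 3,
    effect_size: float = 0.7,
    seed: int = 0,
    occurrence: float = 0.95,
    sv_prob: float = 0.5,
    metabolite_missing_rate: float = 0.05,
    phenotype_beta: float = -0.6,
    phenotype_noise: float = 1.0,
    background_pairs: int = 6,
    background_rho: float = 0.6,
) -> CohortBundle:
    """Cohort with planted SV-confounded bacteria-metabolite associations.

    For each planted triple (species s, KO k, metabolite m): among samples
    where s is present and the KO genotype is 0 (SV-absent strain), the
    metabolite tracks log-abundance through a Gaussian copula tuned to the
    target Spearman rho; among genotype-1 samples the dependence is exactly
    zero by construction.  The phenotype (a fasting-glucose-like scalar) is a
    noisy negative linear function of the planted metabolites' log-levels.

    ``background_pairs`` additional (species, metabolite) pairs carry a
    direct correlation (Spearman ~ ``background_rho``) in *all* present
    samples, independent of any SV genotype: real screen families contain
    many such plain associations, and step-up FDR behaviour depends on how
    many true signals share the family.  The default high ``occurrence``
    mirrors cohorts whose headline species are genotyped in essentially
    every sample.
    """
    if n_samples < 40:
        raise ValueError("need n_samples >= 40 so the 20% subgroup filter can pass")
    if confounded_triples > min(n_species, n_metabolites):
        raise ValueError("more confounded triples than available (species, metabolite) pairs")
    if confounded_triples + background_pairs > n_metabolites:
        raise ValueError("not enough metabolites for planted plus background pairs")
    if not 0.0 <= metabolite_missing_rate < 1.0:
        raise ValueError("metabolite_missing_rate must be in [0,1)")
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"S{i + 1:03d}" for i in range(n_samples)], name="sample_id")
    species = [f"sp_{j + 1:02d}" for j in range(n_species)]
    metabolites = [f"met_{j + 1:02d}" for j in range(n_metabolites)]

    present = rng.random((n_samples, n_species)) < occurrence
    log_abund = rng.normal(0.0, 1.0, size=(n_samples, n_species))
    abundance = pd.DataFrame(
        np.where(present, np.exp(log_abund), 0.0), index=samples, columns=species
    )

    sv_cols = []
    geno = {}
    ko_counter = 0
    species_kos: dict[str, list[str]] = {}
    for j, sp in enumerate(species):
        kos = []
        for _ in range(n_kos_per_species):
            ko_counter += 1
            ko = f"K{20000 + ko_counter:05d}"
            kos.append(ko)
            col = f"{sp}:{ko}"
            sv_cols.append(col)
            g = np.where(present[:, j], (rng.random(n_samples) < sv_prob).astype(float), np.nan)
            geno[col] = g
        species_kos[sp] = kos
    sv_genotype = pd.DataFrame(geno, index=samples, columns=sv_cols)

    # Pearson correlation on the latent normals that yields the target
    # Spearman rho (Gaussian copula relation rho_s = (6/pi) asin(r/2)).
    r = 2.0 * np.sin(np.pi * effect_size / 6.0)
    met_z = rng.normal(0.0, 1.0, size=(n_samples, n_metabolites))
    truth: list[PlantedTriple] = []
    for t in range(confounded_triples):
        sp, met = species[t], metabolites[t]
        ko = species_kos[sp][0]
        col = f"{sp}:{ko}"
        g = sv_genotype[col].to_numpy()
        sv0 = present[:, t] & (g == 0.0)
        met_z[sv0, t] = r * log_abund[sv0, t] + np.sqrt(1 - r * r) * met_z[sv0, t]
        truth.append(PlantedTriple(sp, ko, met, effect_size, sign=1))

    background: list[PlantedTriple] = []
    r_bg = 2.0 * np.sin(np.pi * background_rho / 6.0)
    for b in range(background_pairs):
        sj = (confounded_triples + b) % n_species
        mj = confounded_triples + b
        sp, met = species[sj], metabolites[mj]
        pres = present[:, sj]
        met_z[pres, mj] = (
            r_bg * log_abund[pres, sj] + np.sqrt(1 - r_bg * r_bg) * met_z[pres, mj]
        )
        background.append(PlantedTriple(sp, "", met, background_rho, sign=1))

    pheno = np.zeros(n_samples)
    for t in range(confounded_triples):
        pheno += phenotype_beta * met_z[:, t]
    pheno += phenotype_noise * rng.normal(0.0, 1.0, n_samples)
    phenotype = pd.Series(pheno, index=samples, name="phenotype")

    met_vals = np.exp(met_z)
    miss = rng.random(met_vals.shape) < metabolite_missing_rate
    met_vals = np.where(miss, np.nan, met_vals)
    metabolites_df = pd.DataFrame(met_vals, index=samples, columns=metabolites)

    covariates = pd.DataFrame(
        {
            "age": rng.integers(20, 71, n_samples).astype(float),
            "sex": (rng.random(n_samples) < 0.5).astype(float),
            "bmi": rng.normal(23.0, 3.0, n_samples),
        },
        index=samples,
    )

    return CohortBundle(
        abundance=abundance,
        sv_genotype=sv_genotype,
        metabolites=metabolites_df,
        phenotype=phenotype,
        covariates=covariates,
        truth=truth,
        background=background,
    )
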