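"""Seeded synthetic datasets with planted methylation truth.

The generator emulates the statistical structure of the TT01 methylome study
at desk scale: a random bacterial-like genome (default 500 kb, GC 0.43)
carrying naturally arising occurrences of the eight built-in motifs, dense
gene annotation, per-motif methylation rates above 94%, a small set of
protected (never-methylated) GATC sites biased into promoter regions
(default 22 sites, 20 in promoters), a Dam-overexpression condition that
re-methylates most protected sites (default 18 of 22), an AMP-R-like
condition differing from the reference by a fixed number of planted mark
flips (default 26/3/2+2/4 across motifs I, II, IIIa+IIIb and IV), and
optional GATC-dense 1-kb spikes for the density scan.

Everything is reproducible bit-exactly from (seed, config): a single integer
seed is spawned into independent per-stream generators (genome, truth, SMRT
noise, WGBS noise) so stages can be regenerated independently.

Truth is sampled per genomic position, not per occurrence: two motif strings
whose methylatable base falls on the same (contig, position, strand) share
one state, because one kinetic call at that base would serve both. Protected
and flip sites are drawn from positions not shared between motifs so the
planted counts survive assignment exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import context as ctx
from .genome import GeneFeature, Genome, write_fasta, write_gff
from .motifs import (
    BUILTIN_MOTIFS,
    SMRT_MOTIFS,
    WGBS_MOTIFS,
    MotifSpec,
    compile_iupac,
    scan_all,
    scan_motif,
)
from .smrt import ModificationCall, write_modifications
from .wgbs import CytosineCount, write_cytosine_report

BASELINE_CONDITIONS = ("EP", "LE", "SP", "LS")
DAM_CONDITIONS = ("Control", "DAM+")
AMPR_CONDITION = "AMP-R"
WGBS_CONDITIONS = ("EP", "SP")

#: Per-motif methylation rates emulating the detected fractions of the study
#: (reference condition of the per-motif summary tables).
DEFAULT_DETECTION_PROB: Mapping[str, float] = {
    "motif I": 0.999,
    "motif II": 0.998,
    "motif IIIa": 0.997,
    "motif IIIb": 0.996,
    "motif IV": 0.978,
    "motif V": 1.000,
    "motif VI": 0.948,
    "motif VII": 0.940,
}

#: Planted mark flips between the reference and the AMP-R-like condition
#: (26 in motif I, 3 in motif II, 4 in the bipartite pair, 4 in motif IV).
DEFAULT_AMPR_FLIPS: Mapping[str, int] = {
    "motif I": 26,
    "motif II": 3,
    "motif IIIa": 2,
    "motif IIIb": 2,
    "motif IV": 4,
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic dataset; defaults are the study conditions."""

    seed: int = 0
    genome_length: int = 500_000
    gc: float = 0.43
    contig_id: str = "sim1"
    n_genes: int = 450
    gene_length_mean: float = 900.0
    gene_length_sd: float = 250.0
    min_gene_length: int = 150
    detection_prob: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTION_PROB)
    )
    protected_total: int = 22
    protected_promoter: int = 20
    dam_rescued: int = 18
    ampr_flips: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_AMPR_FLIPS)
    )
    # SMRT call emission
    qv_mean: float = 214.0
    qv_sd: float = 40.0
    min_emitted_qv: float = 30.0  # detection-threshold QV; true calls clip here
    subthreshold_call_prob: float = 0.5  # unmethylated sites emitting a weak call
    subthreshold_qv_range: tuple[float, float] = (5.0, 25.0)
    ipd_mean: float = 5.3
    ipd_sd: float = 0.7
    coverage_mean: float = 148.0
    coverage_sd: float = 25.0
    # WGBS emission
    wgbs_coverage_mean: float = 50.0
    wgbs_meth_rate: float = 0.973
    wgbs_background_rate: float = 0.005
    # density spikes: 1-kb regions packed with extra GATC
    n_density_spikes: int = 2
    spike_gatc_count: int = 40
    spike_size: int = 1000

    def __post_init__(self):
        for name, p in self.detection_prob.items():
            if not 0 <= p <= 1:
                raise ValueError(f"detection probability for {name} outside [0,1]")
        if self.protected_promoter > self.protected_total:
            raise ValueError("protected_promoter cannot exceed protected_total")
        if self.dam_rescued > self.protected_total:
            raise ValueError("dam_rescued cannot exceed protected_total")


class SimulatedDataset:
    """A generated genome + annotation + planted methylation truth.

    Attributes of interest: ``genome``, ``genes``, ``smrt_occurrences`` /
    ``wgbs_occurrences`` (scan tables over the generated genome),
    ``smrt_truth`` / ``wgbs_truth`` (condition -> boolean array aligned to the
    occurrence rows), ``protected_mask`` and ``rescued_mask`` (over SMRT
    rows), and the planted flip indices per motif in ``ampr_flip_indices``.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        ss = np.random.SeedSequence(config.seed)
        s_genome, s_truth, s_smrt, s_wgbs = ss.spawn(4)
        self._rng_genome = np.random.default_rng(s_genome)
        self._rng_truth = np.random.default_rng(s_truth)
        self._smrt_seed = s_smrt
        self._wgbs_seed = s_wgbs
        self._build()

    # ------------------------------------------------------------------ build
    def _build(self) -> None:
        cfg = self.config
        rng = self._rng_genome
        seq = _random_sequence(rng, cfg.genome_length, cfg.gc)
        seq, self.spike_regions = _plant_spikes(rng, seq, cfg)
        self.genome = Genome({cfg.contig_id: seq})
        self.genes = _place_genes(rng, cfg)
        self.smrt_occurrences = scan_all(self.genome, SMRT_MOTIFS)
        self.wgbs_occurrences = scan_all(self.genome, WGBS_MOTIFS)
        self._plant_truth()

    def _plant_truth(self) -> None:
        cfg = self.config
        rng = self._rng_truth
        occ = self.smrt_occurrences

        # group occurrences sharing a methylatable position: one state each
        keys = pd.MultiIndex.from_frame(
            occ[["contig", "methylated_position", "methylated_strand"]]
        )
        group_ids, uniques = pd.factorize(keys)
        group_sizes = np.bincount(group_ids)
        unshared = group_sizes[group_ids] == 1

        probs = occ["motif"].map(cfg.detection_prob).to_numpy(float)
        if np.isnan(probs).any():
            missing = sorted(set(occ["motif"][np.isnan(probs)]))
            raise ValueError(f"no detection probability for motifs {missing}")
        # per-group probability: the max over member motifs
        group_prob = np.zeros(len(uniques))
        np.maximum.at(group_prob, group_ids, probs)

        # protected sites: GATC occurrences at unshared positions, biased
        # into promoter regions per config
        motif1 = (occ["motif"] == "motif I").to_numpy()
        located = ctx.classify_location(occ[motif1], self.genes)
        loc = located["location"].to_numpy()
        cand_idx = occ.index[motif1].to_numpy()
        prom_pool = cand_idx[(loc == "promoter") & unshared[cand_idx]]
        body_pool = cand_idx[(loc == "gene_body") & unshared[cand_idx]]
        n_body = cfg.protected_total - cfg.protected_promoter
        if len(prom_pool) < cfg.protected_promoter or len(body_pool) < n_body:
            raise ValueError(
                "infeasible config: not enough promoter/gene-body GATC sites "
                f"({len(prom_pool)} promoter, {len(body_pool)} gene-body available)"
            )
        protected = np.concatenate(
            [
                rng.choice(prom_pool, cfg.protected_promoter, replace=False),
                rng.choice(body_pool, n_body, replace=False),
            ]
        )
        self.protected_mask = np.zeros(len(occ), dtype=bool)
        self.protected_mask[protected] = True
        protected_groups = np.unique(group_ids[protected])

        rescued_rows = rng.choice(protected, cfg.dam_rescued, replace=False)
        self.rescued_mask = np.zeros(len(occ), dtype=bool)
        self.rescued_mask[rescued_rows] = True

        def sample(protected_state: bool | np.ndarray) -> np.ndarray:
            g = rng.random(len(uniques)) < group_prob
            g[protected_groups] = False
            state = g[group_ids]
            if isinstance(protected_state, np.ndarray):
                state = state | protected_state
            return state

        self.smrt_truth: dict[str, np.ndarray] = {}
        for cond in BASELINE_CONDITIONS:
            self.smrt_truth[cond] = sample(False)
        self.smrt_truth["Control"] = sample(False)
        self.smrt_truth["DAM+"] = sample(self.rescued_mask)

        # AMP-R: copy of the reference with planted, unambiguous flips
        ep = self.smrt_truth[BASELINE_CONDITIONS[0]]
        ampr = ep.copy()
        self.ampr_flip_indices: dict[str, np.ndarray] = {}
        motifs_here = occ["motif"].to_numpy()
        for motif, n_flips in cfg.ampr_flips.items():
            pool = np.flatnonzero(
                (motifs_here == motif) & ep & ~self.protected_mask & unshared
            )
            if len(pool) < n_flips:
                raise ValueError(
                    f"infeasible config: only {len(pool)} flippable sites for {motif}"
                )
            flips = rng.choice(pool, n_flips, replace=False)
            ampr[flips] = False
            self.ampr_flip_indices[motif] = np.sort(flips)
        self.smrt_truth[AMPR_CONDITION] = ampr

        # WGBS truth over the m5C occurrence universe, grouped the same way
        wocc = self.wgbs_occurrences
        wkeys = pd.MultiIndex.from_frame(
            wocc[["contig", "methylated_position", "methylated_strand"]]
        )
        wgroup_ids, wuniques = pd.factorize(wkeys)
        wprobs = wocc["motif"].map(cfg.detection_prob).to_numpy(float)
        wgroup_prob = np.zeros(len(wuniques))
        np.maximum.at(wgroup_prob, wgroup_ids, wprobs)
        self.wgbs_truth: dict[str, np.ndarray] = {}
        for cond in WGBS_CONDITIONS:
            g = rng.random(len(wuniques)) < wgroup_prob
            self.wgbs_truth[cond] = g[wgroup_ids]

    # -------------------------------------------------------------- emission
    @property
    def smrt_conditions(self) -> tuple[str, ...]:
        return BASELINE_CONDITIONS + (AMPR_CONDITION,) + DAM_CONDITIONS

    @property
    def wgbs_conditions(self) -> tuple[str, ...]:
        return WGBS_CONDITIONS

    def smrt_calls(self, condition: str) -> list[ModificationCall]:
        """Kinetic calls for one condition.

        Truth-methylated positions emit one call at or above the detection
        QV; unmethylated positions emit a sub-threshold call with probability
        ``subthreshold_call_prob`` and nothing otherwise. Each distinct
        position emits at most one call.
        """
        cfg = self.config
        truth = self.smrt_truth[condition]
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=self._smrt_seed.entropy,
                spawn_key=self._smrt_seed.spawn_key
                + (self.smrt_conditions.index(condition),),
            )
        )
        occ = self.smrt_occurrences
        seen: set[tuple] = set()
        calls: list[ModificationCall] = []
        for i, row in enumerate(occ.itertuples(index=False)):
            key = (row.contig, row.methylated_position, row.methylated_strand)
            if key in seen:
                continue
            seen.add(key)
            if truth[i]:
                qv = max(float(rng.normal(cfg.qv_mean, cfg.qv_sd)), cfg.min_emitted_qv)
            elif rng.random() < cfg.subthreshold_call_prob:
                qv = float(rng.uniform(*cfg.subthreshold_qv_range))
            else:
                continue
            calls.append(
                ModificationCall(
                    contig=row.contig,
                    position=int(row.methylated_position),
                    strand=row.methylated_strand,
                    mod_type=row.mod_type,
                    qv=qv,
                    ipd_ratio=max(float(rng.normal(cfg.ipd_mean, cfg.ipd_sd)), 1.0),
                    coverage=int(
                        max(rng.normal(cfg.coverage_mean, cfg.coverage_sd), 10)
                    ),
                    condition=condition,
                )
            )
        calls.sort(key=lambda c: (c.contig, c.position, c.strand))
        return calls

    def wgbs_report(self, condition: str) -> list[CytosineCount]:
        """Per-cytosine bisulfite counts for one condition.

        Every cytosine of the genome (C on the plus strand, G positions as
        minus-strand cytosines) gets Poisson coverage; truth-methylated motif
        cytosines draw methylated-read counts at the high rate, everything
        else at the background (conversion-error) rate. Palindromic m5C
        motifs also methylate the complementary-strand cytosine of each
        truth-methylated duplex site.
        """
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence(
                entropy=self._wgbs_seed.entropy,
                spawn_key=self._wgbs_seed.spawn_key
                + (self.wgbs_conditions.index(condition),),
            )
        )
        truth = self.wgbs_truth[condition]
        occ = self.wgbs_occurrences
        counts: list[CytosineCount] = []
        for contig, seq in self.genome.items():
            arr = np.frombuffer(seq.encode(), dtype="S1")
            plus_pos = np.flatnonzero(arr == b"C")
            minus_pos = np.flatnonzero(arr == b"G")
            meth_plus = set(
                int(p)
                for i, p in enumerate(occ["methylated_position"])
                if truth[i] and occ["contig"].iloc[i] == contig
            )
            # duplex partner cytosine on the minus strand (both built-in m5C
            # motifs are palindromic with the partner C opposite start+3)
            starts_by_truth = occ.loc[
                (occ["contig"] == contig) & truth, "start"
            ].to_numpy()
            meth_minus = set(int(s) + 3 for s in starts_by_truth)
            for positions, strand, meth_set in (
                (plus_pos, "+", meth_plus),
                (minus_pos, "-", meth_minus),
            ):
                cov = rng.poisson(cfg.wgbs_coverage_mean, len(positions))
                rates = np.full(len(positions), cfg.wgbs_background_rate)
                is_meth = np.fromiter(
                    (int(p) in meth_set for p in positions),
                    dtype=bool,
                    count=len(positions),
                )
                rates[is_meth] = cfg.wgbs_meth_rate
                meth = rng.binomial(cov, rates)
                counts.extend(
                    CytosineCount(
                        contig=contig,
                        position=int(p),
                        strand=strand,
                        n_methylated=int(m),
                        n_total=int(c),
                        condition=condition,
                    )
                    for p, m, c in zip(positions, meth, cov)
                )
        return counts

    # ----------------------------------------------------------------- files
    def truth_frame(self) -> pd.DataFrame:
        """Tidy truth table: one row per occurrence x condition with the
        planted state plus protected/rescued flags (SMRT and WGBS pooled)."""
        frames = []
        for cond in self.smrt_conditions:
            df = self.smrt_occurrences[
                ["motif", "contig", "methylated_position", "methylated_strand"]
            ].copy()
            df["condition"] = cond
            df["methylated"] = self.smrt_truth[cond]
            df["protected"] = self.protected_mask
            df["rescued"] = self.rescued_mask
            frames.append(df)
        for cond in self.wgbs_conditions:
            df = self.wgbs_occurrences[
                ["motif", "contig", "methylated_position", "methylated_strand"]
            ].copy()
            df["condition"] = f"wgbs:{cond}"
            df["methylated"] = self.wgbs_truth[cond]
            df["protected"] = False
            df["rescued"] = False
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def write_all(self, outdir: str | Path) -> dict[str, Path]:
        """Write genome, annotation, per-condition evidence files and truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["genome"] = outdir / "genome.fa"
        write_fasta(self.genome, paths["genome"])
        paths["genes"] = outdir / "genes.gff3"
        write_gff(self.genes, paths["genes"])
        for cond in self.smrt_conditions:
            safe = cond.replace("+", "plus").replace("-", "_")
            p = outdir / f"modifications_{safe}.gff3"
            write_modifications(self.smrt_calls(cond), p)
            paths[f"smrt:{cond}"] = p
        for cond in self.wgbs_conditions:
            p = outdir / f"cytosine_report_{cond}.tsv"
            write_cytosine_report(self.wgbs_report(cond), p)
            paths[f"wgbs:{cond}"] = p
        paths["truth"] = outdir / "truth.tsv"
        self.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
        return paths


def simulate(config: SimulationConfig | None = None, **kwargs) -> SimulatedDataset:
    """Generate a dataset from a config (or config overrides as kwargs)."""
    if config is None:
        config = SimulationConfig(**kwargs)
    elif kwargs:
        raise TypeError("pass either a config or overrides, not both")
    return SimulatedDataset(config)


# ----------------------------------------------------------------- helpers
def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def _plant_spikes(
    rng: np.random.Generator, seq: str, cfg: SimulationConfig
) -> tuple[str, list[tuple[int, int]]]:
    """Overwrite n non-overlapping 1-kb regions with GATC-dense sequence;
    returns the modified sequence and the spike intervals."""
    if cfg.n_density_spikes == 0:
        return seq, []
    L = len(seq)
    if cfg.n_density_spikes * cfg.spike_size * 2 > L:
        raise ValueError("infeasible config: spikes do not fit the genome")
    arr = list(seq)
    taken: list[tuple[int, int]] = []
    spacing = cfg.spike_size // cfg.spike_gatc_count
    if spacing < 5:
        raise ValueError("spike_gatc_count too high for spike_size")
    for _ in range(cfg.n_density_spikes):
        for _attempt in range(1000):
            start = int(rng.integers(0, L - cfg.spike_size))
            if all(
                start + cfg.spike_size <= s or start >= e for s, e in taken
            ):
                break
        else:
            raise ValueError("could not place density spikes")
        taken.append((start, start + cfg.spike_size))
        for k in range(cfg.spike_gatc_count):
            pos = start + k * spacing
            arr[pos:pos + 4] = list("GATC")
    return "".join(arr), sorted(taken)


def _place_genes(
    rng: np.random.Generator, cfg: SimulationConfig
) -> list[GeneFeature]:
    """Non-overlapping genes with normal-ish lengths and random strands,
    separated by multinomially distributed intergenic gaps."""
    if cfg.n_genes == 0:
        return []
    lengths = np.maximum(
        rng.normal(cfg.gene_length_mean, cfg.gene_length_sd, cfg.n_genes),
        cfg.min_gene_length,
    ).astype(int)
    total_gap = cfg.genome_length - int(lengths.sum())
    if total_gap < cfg.n_genes:
        raise ValueError("infeasible config: more gene sequence than genome")
    gaps = rng.multinomial(total_gap, np.full(cfg.n_genes + 1, 1 / (cfg.n_genes + 1)))
    genes = []
    pos = 0
    for i, glen in enumerate(lengths):
        pos += int(gaps[i])
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneFeature(
                contig=cfg.contig_id,
                start=pos,
                end=pos + int(glen),
                strand=strand,
                gene_id=f"gene_{i + 1:04d}",
            )
        )
        pos += int(glen)
    return genes


def motif_free_background(
    length: int, motifs: Sequence[MotifSpec] = BUILTIN_MOTIFS,
    gc: float = 0.43, seed: int = 0,
) -> str:
    """A random sequence containing no occurrence of any given motif
    (matches are broken by point mutation until the scan comes back empty)."""
    rng = np.random.default_rng(seed)
    seq = list(_random_sequence(rng, length, gc))
    for _round in range(100):
        genome = Genome({"bg": "".join(seq)})
        dirty = False
        for spec in motifs:
            for occ in scan_motif(genome, spec):
                dirty = True
                pos = occ.methylated_position
                current = seq[pos]
                choices = [b for b in "ACGT" if b != current]
                # avoid recreating the motif's own base class
                matcher = compile_iupac(spec.iupac[spec.methylated_offset])
                choices = [b for b in choices if not matcher.fullmatch(b)] or choices
                seq[pos] = choices[int(rng.integers(len(choices)))]
        if not dirty:
            return "".join(seq)
    raise RuntimeError("failed to purge motifs from background sequence")


def planted_motif_genome(
    n_sites: int,
    motif: MotifSpec | None = None,
    gap: int = 60,
    seed: int = 0,
    contig_id: str = "planted",
) -> tuple[Genome, list[int]]:
    """A genome of motif-free background with exactly *n_sites* planted,
    non-overlapping copies of one motif; returns (genome, match starts)."""
    if motif is None:
        motif = BUILTIN_MOTIFS[0]
    unit = gap + len(motif.iupac)
    bg = motif_free_background(n_sites * unit + gap, [motif], seed=seed)
    # realize the degenerate motif as a concrete sequence
    rng = np.random.default_rng(seed + 1)
    concrete = "".join(
        c if c in "ACGT" else {"R": "A", "Y": "C", "S": "G", "W": "A",
                               "K": "G", "M": "A", "B": "C", "D": "A",
                               "H": "A", "V": "A", "N": "A"}[c]
        for c in motif.iupac
    )
    seq = list(bg)
    starts = []
    for k in range(n_sites):
        start = gap + k * unit
        seq[start:start + len(concrete)] = list(concrete)
        starts.append(start)
    # planting can create spurious matches across junctions; break those by
    # mutating a background base inside the unexpected match
    planted = {(s, s + len(concrete)) for s in starts}
    for _round in range(50):
        genome = Genome({contig_id: "".join(seq)})
        extra = [
            o for o in scan_motif(genome, motif)
            if (o.start, o.start + len(concrete)) not in planted
        ]
        if not extra:
            return genome, starts
        for o in extra:
            for pos in range(o.start, o.start + len(concrete)):
                if all(not (s <= pos < e) for s, e in planted):
                    seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[seq[pos]]
                    break
    raise RuntimeError("failed to isolate planted motif copies")
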