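"""Synthetic data with planted, truth-known structure for every pipeline stage.

Three generators emulate the inputs of the analysis:

* a *dataset collection* of many independent expression studies in which one
  planted regulator linearly drives a target module, but only in a
  context-dependent fraction of the studies (regulatory networks are active
  only in some physiological contexts, so per-dataset correlations are strong
  in active studies and absent elsewhere);
* a *four-condition experiment* (WT, WT+IL4, KO, KO+IL4 in replicate) with
  genes planted in the regulation categories I/II/III or left unchanged;
* a *toy genome* with non-overlapping gene models, promoter-planted IUPAC
  motif instances, and per-factor/condition peak files realizing known bound,
  active, poised and latent enhancer configurations.

Every generator is a pure function of its config (including the seed) and
returns a truth record sufficient to score the downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import CONDITIONS, FourConditionExperiment, default_design
from .expression import DatasetCollection, ExpressionDataset

MOTIF_TIMEPOINTS = ("1h", "2h", "4h")


@dataclass
class RegulatorSimConfig:
    """Planted-regulator collection: many studies, context-dependent coupling."""

    n_datasets: int = 40
    samples_per_dataset: int = 10
    n_genes: int = 1000
    module_size: int = 20
    n_decoy_regulators: int = 200
    activity_fraction: float = 0.6  # share of studies where the module is driven
    coupling_slope: float = 1.0     # log2 units of module response per unit regulator
    noise_sd: float = 0.5           # log2-intensity measurement noise
    baseline_mean: float = 8.0      # typical log2 microarray intensity
    baseline_sd: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.module_size >= self.n_genes:
            raise ValueError("module_size must be smaller than n_genes")
        if self.module_size + self.n_decoy_regulators + 1 > self.n_genes:
            raise ValueError("n_genes too small for module + decoys + regulator")
        if self.samples_per_dataset < 6:
            raise ValueError("each dataset needs at least 6 samples")
        if not 0.0 <= self.activity_fraction <= 1.0:
            raise ValueError("activity_fraction must lie in [0, 1]")
        if self.n_datasets < 1:
            raise ValueError("need at least one dataset")


@dataclass
class CategorySimConfig:
    """Four-condition experiment with genes planted in regulation categories.

    Default category sizes follow the lysosomal-gene partition observed in
    IL-4-treated wild-type vs Stat6-deficient macrophages (42 / 82 / 44
    regulated genes) plus a background of unchanged genes.
    """

    n_category_i: int = 42
    n_category_ii: int = 82
    n_category_iii: int = 44
    n_unchanged: int = 100
    replicates_per_condition: int = 3
    effect_size: float = 2.0   # log2 shift of regulated genes
    noise_sd: float = 0.25     # replicate-level log2 noise
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    seed: int = 0

    @property
    def n_genes(self) -> int:
        return self.n_category_i + self.n_category_ii + self.n_category_iii + self.n_unchanged

    def validate(self) -> None:
        if min(self.n_category_i, self.n_category_ii, self.n_category_iii, self.n_unchanged) < 0:
            raise ValueError("category counts must be non-negative")
        if self.replicates_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")
        if self.n_genes == 0:
            raise ValueError("no genes to simulate")


@dataclass
class GenomeSimConfig:
    """Toy genome for peak-annotation, enhancer-state and motif-scan fixtures."""

    n_chromosomes: int = 2
    chrom_length: int = 300_000
    n_genes: int = 30
    promoter_flank: int = 2000
    planted_motif: str = "TTCNNNNGAA"
    peak_width_range: tuple[int, int] = (200, 600)
    tss_window: int = 5000
    n_bound: int = 10    # genes with a consistent TF peak near the TSS
    n_active: int = 4    # bound subset: all three marks pre-stimulus
    n_poised: int = 3    # bound subset: H3K4me1-only pre, H3K27ac gained post (WT only)
    n_latent: int = 2    # bound subset: devoid pre-stimulus, H3K4me1 gained post
    seed: int = 0

    def validate(self) -> None:
        if self.n_bound > self.n_genes:
            raise ValueError("n_bound exceeds n_genes")
        if self.n_active + self.n_poised + self.n_latent > self.n_bound:
            raise ValueError("state subsets exceed the bound gene set")
        per_chrom = -(-self.n_genes // self.n_chromosomes)
        spacing = self.chrom_length // (per_chrom + 1)
        if spacing <= 2 * self.promoter_flank + 2 * self.tss_window:
            raise ValueError("chromosomes too short for non-overlapping gene layout")
        if self.peak_width_range[0] < 2 or self.peak_width_range[0] > self.peak_width_range[1]:
            raise ValueError("invalid peak_width_range")


def simulate_dataset_collection(
    config: RegulatorSimConfig,
) -> tuple[DatasetCollection, dict]:
    """Generate a truth-known collection of independent expression studies.

    In active datasets each module gene is ``baseline + coupling_slope *
    regulator_activity + noise``; elsewhere, and for all decoy regulators and
    background genes, values are independent noise around a per-gene baseline.
    The planted regulator's own measured row tracks the latent activity (plus
    the same measurement noise).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    regulator = "REG1"
    module = [f"MOD{i:04d}" for i in range(1, config.module_size + 1)]
    decoys = [f"DEC{i:04d}" for i in range(1, config.n_decoy_regulators + 1)]
    n_background = config.n_genes - config.module_size - config.n_decoy_regulators - 1
    background = [f"BG{i:05d}" for i in range(1, n_background + 1)]
    genes = [regulator, *module, *decoys, *background]

    n_active = round(config.activity_fraction * config.n_datasets)
    active_idx = set(rng.choice(config.n_datasets, size=n_active, replace=False).tolist())

    datasets = []
    active_ids = []
    for d in range(config.n_datasets):
        ds_id = f"SIM{d + 1:04d}"
        ns, ng = config.samples_per_dataset, len(genes)
        baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=ng)
        noise = rng.normal(0.0, config.noise_sd, size=(ng, ns))
        activity = rng.normal(0.0, 1.0, size=ns)  # latent regulator activity per sample
        values = baseline[:, None] + noise
        values[0] += activity  # measured regulator row tracks its activity
        if d in active_idx:
            values[1 : 1 + config.module_size] += config.coupling_slope * activity
            active_ids.append(ds_id)
        df = pd.DataFrame(
            values, index=genes, columns=[f"S{j + 1:02d}" for j in range(ns)]
        )
        datasets.append(ExpressionDataset(id=ds_id, values=df, platform="synthetic"))

    truth = {
        "regulator": regulator,
        "module": module,
        "decoys": decoys,
        "active_datasets": active_ids,
        "config": asdict(config),
    }
    return DatasetCollection(datasets, namespace=genes), truth


def simulate_four_condition_experiment(
    config: CategorySimConfig,
) -> tuple[FourConditionExperiment, pd.Series]:
    """Four-condition replicate matrix with planted regulation categories.

    Category I genes shift +effect in WT_IL4 only; category II genes shift
    -effect in KO_IL4 only; category III genes shift -effect in both IL4
    conditions; unchanged genes shift nowhere.  Gaussian replicate noise is
    added throughout.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = (
        ["I"] * config.n_category_i
        + ["II"] * config.n_category_ii
        + ["III"] * config.n_category_iii
        + ["unchanged"] * config.n_unchanged
    )
    genes = [f"GENE{i:04d}" for i in range(1, config.n_genes + 1)]
    truth = pd.Series(labels, index=genes, name="category")

    shifts = {c: np.zeros(config.n_genes) for c in CONDITIONS}
    is_i = truth.to_numpy() == "I"
    is_ii = truth.to_numpy() == "II"
    is_iii = truth.to_numpy() == "III"
    shifts["WT_IL4"][is_i] += config.effect_size
    shifts["KO_IL4"][is_ii] -= config.effect_size
    shifts["WT_IL4"][is_iii] -= config.effect_size
    shifts["KO_IL4"][is_iii] -= config.effect_size

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)
    design = default_design(config.replicates_per_condition)
    blocks = {}
    for cond in CONDITIONS:
        mean = baseline + shifts[cond]
        reps = mean[:, None] + rng.normal(
            0.0, config.noise_sd, size=(config.n_genes, config.replicates_per_condition)
        )
        blocks[cond] = pd.DataFrame(reps, index=genes, columns=design[cond])
    values = pd.concat([blocks[c] for c in CONDITIONS], axis=1)
    return FourConditionExperiment(values, design), truth


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)


def _instantiate_motif(rng: np.random.Generator, pattern: str) -> str:
    from .motifs import IUPAC

    return "".join(
        rng.choice(list(IUPAC[sym].replace("N", "") or "ACGT")) for sym in pattern
    )


def simulate_genome_peaks_and_fasta(
    config: GenomeSimConfig,
) -> tuple[pd.DataFrame, dict[str, str], dict[str, pd.DataFrame], dict]:
    """Toy genome with planted TF peaks, chromatin-mark peaks and promoter motifs.

    Returns ``(gene models, genome, peak_sets, truth)`` where ``peak_sets``
    maps keys like ``"TF:1h"`` and ``"H3K4me1:WT"`` to peak tables and
    ``truth`` records the bound / active / poised / latent gene subsets, the
    per-gene TF peak intervals and the planted motif placements.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    # lay out genes evenly, alternating strands, never overlapping
    per_chrom = -(-config.n_genes // config.n_chromosomes)
    spacing = config.chrom_length // (per_chrom + 1)
    models = []
    g = 0
    for c in range(config.n_chromosomes):
        chrom = f"chr{c + 1}"
        for j in range(per_chrom):
            if g >= config.n_genes:
                break
            strand = "+" if g % 2 == 0 else "-"
            anchor = spacing * (j + 1)
            gene_len = 1000
            if strand == "+":
                start, end, tss = anchor, anchor + gene_len, anchor
            else:
                start, end, tss = anchor - gene_len, anchor, anchor - 1
            models.append((f"GENE{g + 1:04d}", chrom, strand, tss, start, end))
            g += 1
    models_df = pd.DataFrame(
        models, columns=["symbol", "chrom", "strand", "tss", "start", "end"]
    )

    # genome sequence with motif instances planted in promoter windows
    genome_arr = {
        f"chr{c + 1}": _random_dna(rng, config.chrom_length)
        for c in range(config.n_chromosomes)
    }
    motif_truth = []
    flank = config.promoter_flank
    for _, gene in models_df.iterrows():
        # one planted instance per gene, placed on the forward genomic strand
        window_offset = int(rng.integers(10, 2 * flank - len(config.planted_motif) - 10))
        lo = gene["tss"] - flank
        if gene["strand"] == "+":
            genomic = lo + window_offset
        else:
            # window is reverse-complemented for "-" genes: window offset o
            # maps to genomic position tss + flank - o - len(motif)
            genomic = gene["tss"] + flank - window_offset - len(config.planted_motif)
        instance = _instantiate_motif(rng, config.planted_motif)
        seq = instance if gene["strand"] == "+" else None
        if gene["strand"] == "-":
            from .motifs import reverse_complement

            seq = reverse_complement(instance)
        genome_arr[gene["chrom"]][genomic : genomic + len(instance)] = np.frombuffer(
            seq.encode(), dtype="S1"
        )
        motif_truth.append(
            {
                "gene": gene["symbol"],
                "window_offset": window_offset,
                "genomic_start": int(genomic),
                "instance": instance,
            }
        )
    genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}

    # the bound genes carry a reproducible TF peak; enhancer states are planted
    # on those very peak regions (active/poised/latent subsets of the bound set)
    order = rng.permutation(config.n_genes)
    bound_unsorted = list(models_df["symbol"].iloc[order[: config.n_bound]])
    bound = sorted(bound_unsorted)
    active = sorted(bound_unsorted[: config.n_active])
    poised = sorted(bound_unsorted[config.n_active : config.n_active + config.n_poised])
    latent = sorted(
        bound_unsorted[
            config.n_active + config.n_poised :
            config.n_active + config.n_poised + config.n_latent
        ]
    )

    by_symbol = models_df.set_index("symbol")

    def peak_near(symbol: str, max_offset: int, width: int) -> tuple[str, int, int]:
        gene = by_symbol.loc[symbol]
        center = int(gene["tss"] + rng.integers(-max_offset, max_offset + 1))
        start = max(0, center - width // 2)
        return gene["chrom"], start, start + width

    wmin, wmax = config.peak_width_range
    peak_sets: dict[str, list[tuple]] = {}

    # consistent TF peaks near bound-gene TSSs at every timepoint (center
    # within +/- tss_window after the small per-timepoint jitter)
    base_peaks = {}
    for sym in bound:
        width = int(rng.integers(wmin, wmax + 1))
        base_peaks[sym] = peak_near(sym, config.tss_window - wmax, width)
    for t, tp in enumerate(MOTIF_TIMEPOINTS):
        rows = []
        for sym in bound:
            chrom, start, end = base_peaks[sym]
            jitter = int(rng.integers(-wmin // 4, wmin // 4 + 1))
            rows.append((chrom, start + jitter, end + jitter, f"TF_{sym}_{tp}", f"TF:{tp}"))
        # one irreproducible decoy peak per timepoint: disjoint positions across
        # timepoints, far from any TSS window, so the consistency merge drops it
        decoy_start = int(spacing // 2 + t * 2 * wmin)
        rows.append(
            ("chr1", decoy_start, decoy_start + wmin, f"TF_decoy_{tp}", f"TF:{tp}")
        )
        peak_sets[f"TF:{tp}"] = rows

    # chromatin-mark peaks per condition (pre = no IL-4, post = + IL-4)
    mark_conditions = [
        ("H3K4me1", "WT"), ("H3K4me1", "WT_IL4"), ("H3K4me1", "KO"), ("H3K4me1", "KO_IL4"),
        ("H3K27ac", "WT"), ("H3K27ac", "WT_IL4"), ("H3K27ac", "KO"), ("H3K27ac", "KO_IL4"),
        ("Pu1", "WT"), ("Pu1", "WT_IL4"), ("Pu1", "KO"), ("Pu1", "KO_IL4"),
    ]
    mark_rows: dict[str, list[tuple]] = {f"{m}:{c}": [] for m, c in mark_conditions}

    def add_mark(sym: str, mark: str, conditions: list[str]) -> None:
        # mark nucleosomes sit on the TF peak region so overlap flags are exercised
        chrom, pk_start, pk_end = base_peaks[sym]
        pad = int(rng.integers(0, wmin // 2))
        start = max(0, pk_start - pad)
        end = pk_end + pad
        for cond in conditions:
            key = f"{mark}:{cond}"
            mark_rows[key].append((chrom, start, end, f"{mark}_{sym}_{cond}", key))

    everywhere = ["WT", "WT_IL4", "KO", "KO_IL4"]
    for sym in active:     # all three marks pre-stimulation, in both genotypes
        add_mark(sym, "H3K4me1", everywhere)
        add_mark(sym, "H3K27ac", everywhere)
        add_mark(sym, "Pu1", everywhere)
    for sym in poised:     # H3K4me1-only pre; H3K27ac gained post in WT only
        add_mark(sym, "H3K4me1", everywhere)
        add_mark(sym, "H3K27ac", ["WT_IL4"])
    for sym in latent:     # devoid pre; H3K4me1 gained post (both genotypes)
        add_mark(sym, "H3K4me1", ["WT_IL4", "KO_IL4"])

    peaks = {
        key: pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "source"])
        for key, rows in {**peak_sets, **mark_rows}.items()
    }

    expected_state = {}
    for sym in bound:
        if sym in active:
            expected_state[sym] = "active"
        elif sym in poised:
            expected_state[sym] = "poised_activated"
        elif sym in latent:
            expected_state[sym] = "latent"
        else:
            expected_state[sym] = "other"
    truth = {
        "bound": bound,
        "poised": poised,
        "active": active,
        "latent": latent,
        "expected_state": expected_state,
        "stat6_dependent": {sym: (sym in poised) for sym in bound},
        "motifs": motif_truth,
        "config": {**asdict(config), "peak_width_range": list(config.peak_width_range)},
    }
    return models_df, genome, peaks, truth


# ---------------------------------------------------------------------------
# writers


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: pd.DataFrame, path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for _, gene in models.iterrows():
        lines.append(
            "\t".join(
                [
                    gene["chrom"], "synexpress", "gene",
                    str(int(gene["start"]) + 1), str(int(gene["end"])),
                    ".", gene["strand"], ".",
                    f"ID={gene['symbol']};Name={gene['symbol']}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_genome_fixture(
    config: GenomeSimConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, dict[str, str], dict[str, pd.DataFrame], dict]:
    """Generate and write the toy genome fixture (FASTA, GFF3, BEDs, truth JSON)."""
    from .peaks import write_bed

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    models, genome, peaks, truth = simulate_genome_peaks_and_fasta(config)
    write_fasta(genome, out / "genome.fa")
    write_gff3(models, out / "genes.gff3")
    for key, table in peaks.items():
        write_bed(table, out / f"peaks_{key.replace(':', '_')}.bed")
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return models, genome, peaks, truth
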