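"""Synthetic colony-size screens with the statistical structure the
analysis pipeline assumes.

The generator emulates a pombe-epistasis-mapper style screen: a query strain
crossed against a deletion library, arrayed as 4 or 12 replicate spots per
gene on fixed-geometry plates, photographed as paired control plates (no
double-mutant selection) and test plates (double mutants selected).  The
generative model is multiplicative and lognormal:

    size = baseline * interaction_effect(gene)      [test plates only]
                    * plate_effect                   [lognormal, per plate]
                    * edge_boost                     [outermost two rows/cols]
                    * noise                          [lognormal, mean 1]

and a small ``missing_rate`` of spots is zeroed (dead colonies).  Planted
synthetic-sick and synthetic-rescue genes multiply the double-mutant size by
``sick_effect`` (< 1) or ``rescue_effect`` (> 1).  A small genome with gene
coordinates and GMT gene-set labels accompanies the colony tables so linkage
filtering and enrichment are exercisable end to end.

Planted interactors are drawn from genes *outside* the query linkage windows:
genes linked to the query locus cannot segregate away from it during the
cross, so the screen is structurally blind to them, and planting an
interaction there would be unobservable by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as sio
from .errors import ConfigurationError, LayoutError
from .linkage import LinkageWindow

TRUTH_COLUMNS = ["gene", "interaction", "effect"]

_PLANTED_SET_ID = "SET_PLANTED"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic screen.

    Sizes are in the same arbitrary colony-area units as real screen tables;
    the hit-calling size-difference threshold of 25 is meaningful relative to
    the default ``baseline_size`` of 100.
    """

    n_genes: int = 500
    plate_rows: int = 16
    plate_cols: int = 24
    replicates_per_gene: int = 4
    n_experiments: int = 1
    baseline_size: float = 100.0
    plate_effect_sd: float = 0.1
    edge_boost: float = 1.3
    noise_cv: float = 0.1
    sick_fraction: float = 0.05
    rescue_fraction: float = 0.02
    sick_effect: float = 0.5
    rescue_effect: float = 1.5
    missing_rate: float = 0.01
    chromosome_lengths: Sequence[int] = (5_579_000, 4_539_000, 2_452_000)
    query_loci: Sequence[tuple[str, int]] = (("chr2", 2_000_000), ("chr1", 4_000_000))
    linkage_half_width: int = 500_000
    n_gene_sets: int = 25
    gene_set_size: int = 30
    planted_set_sick_share: float = 0.5
    screen_id: str = "screen"
    temperature: str = "25C"
    seed: int = 0

    def __post_init__(self):
        counts = {
            "n_genes": self.n_genes,
            "plate_rows": self.plate_rows,
            "plate_cols": self.plate_cols,
            "replicates_per_gene": self.replicates_per_gene,
            "n_experiments": self.n_experiments,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        for name in ("baseline_size", "edge_boost", "sick_effect", "rescue_effect"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        for name in ("plate_effect_sd", "noise_cv"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("sick_fraction", "rescue_fraction", "missing_rate",
                     "planted_set_sick_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.sick_fraction + self.rescue_fraction > 1.0:
            raise ConfigurationError("sick_fraction + rescue_fraction must be <= 1")
        if self.plate_rows < 5 or self.plate_cols < 5:
            raise ConfigurationError("plates need >= 5 rows and columns for a middle")
        if self.replicates_per_gene > self.plate_rows * self.plate_cols:
            raise LayoutError(
                f"{self.replicates_per_gene} replicate spots exceed the "
                f"{self.plate_rows}x{self.plate_cols} plate capacity"
            )
        if self.linkage_half_width <= 0:
            raise ConfigurationError("linkage_half_width must be > 0")
        chrom_names = self._chromosome_names()
        for chrom, center in self.query_loci:
            if chrom not in chrom_names:
                raise ConfigurationError(f"query locus on unknown chromosome {chrom!r}")
            if not 0 <= center < self.chromosome_lengths[chrom_names.index(chrom)]:
                raise ConfigurationError(f"query locus {chrom}:{center} off chromosome")

    def _chromosome_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chromosome_lengths))]

    @property
    def genes_per_plate(self) -> int:
        return (self.plate_rows * self.plate_cols) // self.replicates_per_gene

    @property
    def n_plates(self) -> int:
        return math.ceil(self.n_genes / self.genes_per_plate)

    def windows(self) -> list[LinkageWindow]:
        return [
            LinkageWindow(chromosome=c, center=p, half_width=self.linkage_half_width)
            for c, p in self.query_loci
        ]


@dataclass
class SimulatedScreen:
    """A generated screen: colony tables plus ground truth and annotations."""

    colonies: pd.DataFrame
    truth: pd.DataFrame
    annotations: pd.DataFrame
    gene_sets: dict[str, list[str]]
    windows: list[LinkageWindow]
    planted_set_id: str
    config: SimulationConfig

    @property
    def control(self) -> pd.DataFrame:
        return self.colonies[self.colonies["condition"] == "control"]

    @property
    def test(self) -> pd.DataFrame:
        return self.colonies[self.colonies["condition"] == "test"]


def _layout(config: SimulationConfig) -> pd.DataFrame:
    """Fixed spot layout shared by every plate pair: gene and replicate per
    grid position, row-major, one contiguous replicate block per gene.

    The final plate may be partially spotted; unassigned positions carry the
    sentinel gene ``EMPTY`` with size 0 downstream.
    """
    rows, cols = config.plate_rows, config.plate_cols
    capacity = rows * cols
    gpp = config.genes_per_plate
    records = []
    for plate_idx in range(config.n_plates):
        first = plate_idx * gpp
        genes = [f"g{first + j:04d}" for j in range(min(gpp, config.n_genes - first))]
        pos = 0
        for gene in genes:
            for rep in range(1, config.replicates_per_gene + 1):
                records.append((plate_idx + 1, pos // cols + 1, pos % cols + 1, gene, rep))
                pos += 1
        n_empty = 0
        while pos < capacity:
            n_empty += 1
            records.append((plate_idx + 1, pos // cols + 1, pos % cols + 1,
                            sio.EMPTY_GENE, n_empty))
            pos += 1
    return pd.DataFrame(records, columns=["plate", "row", "col", "gene", "replicate"])


def _edge_mask(layout: pd.DataFrame, config: SimulationConfig) -> np.ndarray:
    r, c = layout["row"].to_numpy(), layout["col"].to_numpy()
    return (
        (r <= 2) | (r > config.plate_rows - 2) | (c <= 2) | (c > config.plate_cols - 2)
    )


def _plant_interactions(
    genes: list[str], unlinked: set[str], config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    n_sick = round(config.sick_fraction * len(genes))
    n_rescue = round(config.rescue_fraction * len(genes))
    eligible = sorted(g for g in genes if g in unlinked)
    if n_sick + n_rescue > len(eligible):
        raise ConfigurationError(
            "not enough unlinked genes to host the planted interactions"
        )
    picked = rng.choice(len(eligible), size=n_sick + n_rescue, replace=False)
    sick = {eligible[i] for i in picked[:n_sick]}
    rescue = {eligible[i] for i in picked[n_sick:]}
    cls = [
        "sick" if g in sick else "rescue" if g in rescue else "none" for g in genes
    ]
    eff = [
        config.sick_effect if g in sick
        else config.rescue_effect if g in rescue
        else 1.0
        for g in genes
    ]
    return pd.DataFrame({"gene": genes, "interaction": cls, "effect": eff})


def _place_genes(
    genes: list[str], config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Uniform gene placement over the genome, one gene forced into each
    query window so linkage filtering always has work to do."""
    names = config._chromosome_names()
    lengths = np.asarray(config.chromosome_lengths, dtype=float)
    n = len(genes)
    chrom_idx = rng.choice(len(lengths), size=n, p=lengths / lengths.sum())
    gene_len = rng.integers(800, 2500, size=n)
    starts = np.floor(rng.random(n) * (lengths[chrom_idx] - gene_len)).astype(np.int64)
    ann = pd.DataFrame(
        {
            "gene": genes,
            "chromosome": [names[i] for i in chrom_idx],
            "start": starts,
            "end": starts + gene_len,
        }
    )
    # guarantee >= 1 gene inside each query window
    for qi, (chrom, center) in enumerate(config.query_loci):
        near = (ann["chromosome"] == chrom) & (
            (ann["start"] - center).abs() <= config.linkage_half_width
        )
        if not near.any():
            j = ann.index[qi % len(ann)]
            ann.loc[j, "chromosome"] = chrom
            ann.loc[j, "start"] = max(0, center - 50_000)
            ann.loc[j, "end"] = ann.loc[j, "start"] + 1_500
    return ann


def _make_gene_sets(
    truth: pd.DataFrame,
    unlinked: set[str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """One planted set supplying ``planted_set_sick_share`` of the true sick
    genes, plus random decoy sets."""
    genes = truth["gene"].tolist()
    sick = truth.loc[truth["interaction"] == "sick", "gene"].tolist()
    n_from_sick = round(config.planted_set_sick_share * len(sick))
    planted = list(rng.choice(sick, size=n_from_sick, replace=False)) if n_from_sick else []
    null_pool = sorted(set(g for g in genes if g in unlinked) - set(sick))
    n_fill = max(config.gene_set_size - len(planted), 0)
    planted += list(rng.choice(null_pool, size=min(n_fill, len(null_pool)), replace=False))
    sets: dict[str, list[str]] = {_PLANTED_SET_ID: sorted(planted)}
    for i in range(max(config.n_gene_sets - 1, 0)):
        members = rng.choice(genes, size=min(config.gene_set_size, len(genes)),
                             replace=False)
        sets[f"SET_{i + 1:03d}"] = sorted(members)
    return sets


def simulate_screen(config: SimulationConfig) -> SimulatedScreen:
    """Generate paired control/test plates for ``n_experiments`` experiments,
    the truth table of planted interactions, gene coordinates, and gene sets.

    Control and test plates share the spot layout exactly, so every control
    spot has a position-matched test spot (the pairing the scorer relies on).
    Fixing ``config.seed`` reproduces the output byte-identically.
    """
    root = np.random.SeedSequence(config.seed)
    ss_classes, ss_coords, ss_sets, *ss_exps = root.spawn(3 + config.n_experiments)

    layout = _layout(config)
    genes = [f"g{i:04d}" for i in range(config.n_genes)]
    annotations = _place_genes(genes, config, np.random.default_rng(ss_coords))

    from .linkage import flag_linked  # local import to avoid cycle at module load

    linked = flag_linked(annotations, config.windows())
    unlinked = set(linked.index[~linked])
    truth = _plant_interactions(genes, unlinked, config,
                                np.random.default_rng(ss_classes))
    gene_sets = _make_gene_sets(truth, unlinked, config,
                                np.random.default_rng(ss_sets))

    effect = truth.set_index("gene")["effect"]
    gene_effect = layout["gene"].map(effect).fillna(1.0).to_numpy()
    edge = _edge_mask(layout, config)
    sigma = math.sqrt(math.log1p(config.noise_cv**2))
    n_spots = len(layout)

    frames = []
    for e, ss in enumerate(ss_exps, start=1):
        rng = np.random.default_rng(ss)
        for condition in ("control", "test"):
            sizes = np.full(n_spots, config.baseline_size)
            if condition == "test":
                sizes = sizes * gene_effect
            plate_mult = np.exp(rng.normal(0.0, config.plate_effect_sd,
                                           size=config.n_plates))
            sizes = sizes * plate_mult[layout["plate"].to_numpy() - 1]
            sizes = np.where(edge, sizes * config.edge_boost, sizes)
            if sigma > 0:
                noise = np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=n_spots))
                sizes = sizes * noise
            if config.missing_rate > 0:
                sizes = np.where(rng.random(n_spots) < config.missing_rate, 0.0, sizes)
            sizes = np.where(layout["gene"].to_numpy() == sio.EMPTY_GENE, 0.0, sizes)
            frames.append(
                pd.DataFrame(
                    {
                        "screen_id": config.screen_id,
                        "experiment_id": f"exp{e}",
                        "condition": condition,
                        "temperature": config.temperature,
                        "plate_id": [
                            f"exp{e}_{condition}_p{p:02d}" for p in layout["plate"]
                        ],
                        "row": layout["row"],
                        "col": layout["col"],
                        "gene": layout["gene"],
                        "replicate": layout["replicate"],
                        "size": sizes,
                    }
                )
            )
    colonies = pd.concat(frames, ignore_index=True)
    return SimulatedScreen(
        colonies=colonies,
        truth=truth,
        annotations=annotations,
        gene_sets=gene_sets,
        windows=config.windows(),
        planted_set_id=_PLANTED_SET_ID,
        config=config,
    )


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write the planted-interaction truth table as TSV (lossless round-trip)."""
    truth.loc[:, TRUTH_COLUMNS].to_csv(path, sep="\t", index=False,
                                       float_format="%.10g")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene": str, "interaction": str})
    if list(df.columns) != TRUTH_COLUMNS:
        from .errors import FormatError

        raise FormatError(f"{path}: expected columns {TRUTH_COLUMNS}")
    df["effect"] = df["effect"].astype(float)
    return df


def write_screen(screen: SimulatedScreen, out_dir) -> dict[str, str]:
    """Write a simulated screen to ``out_dir`` (colonies.tsv, truth.tsv,
    genes.bed, sets.gmt, windows.txt); returns the paths written."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "colonies": os.path.join(out_dir, "colonies.tsv"),
        "truth": os.path.join(out_dir, "truth.tsv"),
        "bed": os.path.join(out_dir, "genes.bed"),
        "gmt": os.path.join(out_dir, "sets.gmt"),
        "windows": os.path.join(out_dir, "windows.txt"),
    }
    sio.write_colony_table(screen.colonies, paths["colonies"])
    write_truth(screen.truth, paths["truth"])
    sio.write_bed(screen.annotations, paths["bed"])
    sio.write_gmt(screen.gene_sets, paths["gmt"])
    with open(paths["windows"], "w") as fh:
        for w in screen.windows:
            fh.write(f"{w.chromosome}:{w.center}+-{w.half_width}\n")
    return paths
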