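"""Seeded generators for every input the quantification pipeline consumes.

Three substrates are emulated:

* **site-spanning reads** — per cell, each read is a random flank, the
  endogenous or exogenous site (allele ~ Bernoulli of the group's exogenous
  fraction, strand ~ Bernoulli(0.5)), another random flank, then uniform
  per-base substitution error.  The true allele of every read is recorded.
* **per-cell count tables** — the gene of interest follows a negative
  binomial (var = mu + dispersion*mu^2) whose group means encode expression
  fold-changes relative to control; sequencing depth is lognormal; filler
  and mitochondrial pseudo-genes are emitted so the QC filters have
  something to act on.
* **qPCR plates** — a control sample with a fixed ΔCt and a test sample
  whose ΔCt is shifted by −log2(residual expression), with Gaussian cycle
  noise per replicate.

All generators are pure functions of (config, seed): the same seed yields
byte-identical output.  A ground-truth ledger accompanies every dataset so
estimators can be scored without external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .allele_quant import CellRecord, SiteSignature
from .qc_stats import QPCRMeasurement

__all__ = [
    "GroupConfig",
    "SimulationConfig",
    "SimulationTruth",
    "paper_groups_preset",
    "default_signature",
    "simulate_cell_reads",
    "simulate_site_reads",
    "simulate_expression_table",
    "simulate_qpcr",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# the worked-example site pair: endogenous RNAi target and its synonymously
# recoded exogenous counterpart
ENDO_SITE = "GACGATCATGTACAGGACCGG"
EXO_SITE = "CACTATCATATATAGTACTGG"


def default_signature() -> SiteSignature:
    return SiteSignature(endo_site=ENDO_SITE, exo_site=EXO_SITE)


@dataclass(frozen=True)
class GroupConfig:
    """Ground truth for one experimental group."""

    name: str
    n_cells: int = 12
    exo_fraction: float = 0.0        # true exogenous fraction of site reads
    mean_tmc1_cpm: float = 300.0     # group mean expression of the gene (CPM)
    nb_dispersion: float = 0.2       # var = mu + dispersion * mu^2
    site_reads_per_cell: int = 200

    def __post_init__(self) -> None:
        if not (0.0 <= self.exo_fraction <= 1.0):
            raise ValueError("exo_fraction must be in [0, 1]")
        if self.n_cells < 1 or self.site_reads_per_cell < 0:
            raise ValueError("n_cells and site_reads_per_cell must be positive")
        if self.mean_tmc1_cpm <= 0 or self.nb_dispersion < 0:
            raise ValueError("mean_tmc1_cpm must be >0 and dispersion >=0")


@dataclass(frozen=True)
class SimulationConfig:
    groups: tuple[GroupConfig, ...]
    read_length: int = 100
    per_base_error_rate: float = 0.005
    mean_depth: float = 1_000_000.0
    depth_sigma: float = 0.35        # lognormal sigma of per-cell depth
    n_filler_genes: int = 200
    n_mito_genes: int = 10
    mito_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        if not self.groups:
            raise ValueError("at least one group required")
        if not (0.0 <= self.per_base_error_rate < 1.0):
            raise ValueError("per_base_error_rate must be in [0, 1)")

    def validate_read_length(self, site_length: int) -> None:
        if self.read_length < site_length + 2:
            raise ValueError("read_length must be >= site length + 2")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimulationTruth:
    """Ledger of the ground truth behind one simulated dataset."""

    per_cell: dict[str, dict] = field(default_factory=dict)
    per_group: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps({"per_cell": self.per_cell, "per_group": self.per_group}, indent=1)
        )


def paper_groups_preset(seed: int = 0) -> SimulationConfig:
    """The four study groups with their published ground truths.

    Untreated WT and Bth/+ controls are fully endogenous at the control mean;
    the two RNAi + replacement groups carry exogenous fractions 0.764 and
    0.965 and expression fold-changes 1.836 and 3.48 over control.
    """
    control_cpm = 300.0
    return SimulationConfig(
        groups=(
            GroupConfig("WT_control", exo_fraction=0.0, mean_tmc1_cpm=control_cpm),
            GroupConfig("Bth_control", exo_fraction=0.0, mean_tmc1_cpm=control_cpm),
            GroupConfig(
                "RNAi_replacement", exo_fraction=0.764, mean_tmc1_cpm=control_cpm * 1.836
            ),
            GroupConfig(
                "RNAi_replacement_WPRE", exo_fraction=0.965, mean_tmc1_cpm=control_cpm * 3.48
            ),
        ),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# site-spanning reads
# ---------------------------------------------------------------------------

def _random_bases(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _apply_errors(rng: np.random.Generator, read: str, rate: float) -> str:
    if rate <= 0:
        return read
    arr = np.frombuffer(read.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        # substitute with one of the three other bases, uniformly
        others = _BASES[_BASES != arr[i]]
        arr[i] = others[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _rc(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_cell_reads(
    rng: np.random.Generator,
    n_reads: int,
    exo_fraction: float,
    signature: SiteSignature,
    read_length: int = 100,
    error_rate: float = 0.005,
    cell_id: str = "cell",
) -> tuple[list[tuple[str, str]], dict]:
    """Site-spanning reads for one cell, plus the per-read truth.

    Each read embeds one allele site at a random position between random
    flanks, on a random strand, then suffers uniform substitution error.
    Returns ``[(read_id, bases), ...]`` and a truth dict with the planted
    endo/exo counts.
    """
    site_len = signature.site_length
    if read_length < site_len + 2:
        raise ValueError("read_length must be >= site length + 2")
    reads = []
    n_exo_true = 0
    for k in range(n_reads):
        is_exo = bool(rng.random() < exo_fraction)
        n_exo_true += is_exo
        site = signature.exo_site if is_exo else signature.endo_site
        if rng.random() < 0.5:
            site = _rc(site)
        start = int(rng.integers(1, read_length - site_len))
        read = (
            _random_bases(rng, start)
            + site
            + _random_bases(rng, read_length - site_len - start)
        )
        read = _apply_errors(rng, read, error_rate)
        reads.append((f"{cell_id}:read{k}", read))
    truth = {"n_reads": n_reads, "n_exo_true": n_exo_true, "n_endo_true": n_reads - n_exo_true}
    return reads, truth


def _write_fastq(path: Path, reads: list[tuple[str, str]]) -> None:
    import gzip

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rid, bases in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{'I' * len(bases)}\n")


def simulate_site_reads(
    config: SimulationConfig,
    signature: SiteSignature | None = None,
    out_dir: str | Path | None = None,
    compress: bool = False,
) -> tuple[dict[str, list[tuple[str, str]]], SimulationTruth]:
    """Simulate site-spanning reads for every cell of every group.

    Returns ``{cell_id: reads}`` plus the truth ledger; when ``out_dir`` is
    given, one FASTQ per cell and a ``manifest.tsv`` (cell_id, group, fastq)
    are written as well.
    """
    signature = signature or default_signature()
    config.validate_read_length(signature.site_length)
    rng = np.random.default_rng(config.seed)
    reads_by_cell: dict[str, list[tuple[str, str]]] = {}
    truth = SimulationTruth()
    manifest_rows = []
    for group in config.groups:
        n_exo_total = n_total = 0
        for c in range(group.n_cells):
            cell_id = f"{group.name}_c{c:03d}"
            reads, cell_truth = simulate_cell_reads(
                rng,
                group.site_reads_per_cell,
                group.exo_fraction,
                signature,
                config.read_length,
                config.per_base_error_rate,
                cell_id=cell_id,
            )
            reads_by_cell[cell_id] = reads
            truth.per_cell[cell_id] = {"group": group.name, **cell_truth}
            n_exo_total += cell_truth["n_exo_true"]
            n_total += cell_truth["n_reads"]
            manifest_rows.append({"cell_id": cell_id, "group": group.name})
        truth.per_group[group.name] = {
            "exo_fraction_config": group.exo_fraction,
            "exo_fraction_realized": (n_exo_total / n_total) if n_total else None,
        }
    if out_dir is not None:
        out_dir = Path(out_dir)
        fastq_dir = out_dir / "fastq"
        fastq_dir.mkdir(parents=True, exist_ok=True)
        ext = ".fastq.gz" if compress else ".fastq"
        for row in manifest_rows:
            path = fastq_dir / f"{row['cell_id']}{ext}"
            _write_fastq(path, reads_by_cell[row["cell_id"]])
            # relative to the manifest so the dataset directory is relocatable
            row["fastq"] = f"fastq/{row['cell_id']}{ext}"
        pd.DataFrame(manifest_rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return reads_by_cell, truth


# ---------------------------------------------------------------------------
# expression count table
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative binomial with var = mean + dispersion * mean^2.

    dispersion == 0 is the degenerate limit: every draw equals round(mean).
    """
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return np.full(size, round(mean), dtype=np.int64)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size).astype(np.int64)


def simulate_expression_table(
    config: SimulationConfig,
    gene: str = "Tmc1",
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, list[CellRecord], SimulationTruth]:
    """Simulate a cells x genes count table with known group expression means.

    The gene of interest is negative-binomial with mean
    ``mean_tmc1_cpm * depth / 1e6`` per cell; filler genes are Poisson with
    lognormal gene weights, and mitochondrial pseudo-genes (``mt-*``) absorb
    ``mito_fraction`` of the depth.  CellRecords use the realised row sums
    as total mapped reads, so CPM recomputed from the table is coherent.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    filler = [f"gene{i:04d}" for i in range(config.n_filler_genes)]
    mito = [f"mt-{i}" for i in range(config.n_mito_genes)]
    genes = [gene] + filler + mito

    # fixed relative abundances for filler genes (drawn once per dataset)
    weights = rng.lognormal(0.0, 1.0, config.n_filler_genes)
    weights = weights / weights.sum() * (1.0 - config.mito_fraction)
    mito_w = np.full(config.n_mito_genes, config.mito_fraction / max(config.n_mito_genes, 1))

    rows, cells, truth = [], [], SimulationTruth()
    index = []
    for group in config.groups:
        depths = rng.lognormal(
            math.log(config.mean_depth) - config.depth_sigma**2 / 2,
            config.depth_sigma,
            group.n_cells,
        )
        for c, depth in enumerate(depths):
            cell_id = f"{group.name}_c{c:03d}"
            tmc1 = int(
                _nb_draw(rng, group.mean_tmc1_cpm * depth / 1e6, group.nb_dispersion, 1)[0]
            )
            filler_counts = rng.poisson(weights * depth)
            mito_counts = rng.poisson(mito_w * depth)
            row = np.concatenate(([tmc1], filler_counts, mito_counts))
            rows.append(row)
            index.append(cell_id)
            total = int(row.sum())
            cells.append(
                CellRecord(
                    cell_id=cell_id,
                    group=group.name,
                    total_mapped_reads=total,
                    tmc1_raw_count=tmc1,
                )
            )
            truth.per_cell[cell_id] = {
                "group": group.name,
                "true_mean_cpm": group.mean_tmc1_cpm,
                "tmc1_raw": tmc1,
                "depth": total,
            }
        truth.per_group[group.name] = {
            "mean_tmc1_cpm": group.mean_tmc1_cpm,
            "exo_fraction": group.exo_fraction,
        }
    table = pd.DataFrame(rows, index=index, columns=genes)
    return table, cells, truth


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

def simulate_qpcr(
    true_residual_expression: float,
    ct_noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 3,
    control_target_ct: float = 20.0,
    reference_ct: float = 15.0,
) -> tuple[QPCRMeasurement, QPCRMeasurement]:
    """Simulate a (test, control) qPCR pair for a known residual expression.

    The control sample has a fixed ΔCt; the test sample's target Ct is
    shifted by −log2(residual) plus Gaussian noise per replicate, so with no
    noise the ΔΔCt method recovers the residual exactly.
    """
    if not (0.0 < true_residual_expression <= 1.0):
        raise ValueError("residual expression must be in (0, 1]")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shift = -math.log2(true_residual_expression)
    noise = rng.normal(0.0, ct_noise_sd, n_replicates) if ct_noise_sd > 0 else np.zeros(n_replicates)
    test = QPCRMeasurement(
        sample="test",
        target_ct=tuple(control_target_ct + shift + noise),
        reference_ct=(reference_ct,) * n_replicates,
    )
    control = QPCRMeasurement(
        sample="control",
        target_ct=(control_target_ct,) * n_replicates,
        reference_ct=(reference_ct,) * n_replicates,
    )
    return test, control
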