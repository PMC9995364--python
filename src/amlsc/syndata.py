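"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates the statistical structure its downstream consumer
assumes — not a transcriptome-scale simulation:

* ``gen_reads`` plants the 4-nt TCTG tandem duplication in a fraction of
  transcripts of leukemic cells and emits barcoded, UMI-tagged read windows
  over the locus, including boundary-truncated mutant patterns.
* ``gen_counts`` draws negative-binomial counts with log-normal per-gene
  dispersion, halves chromosome-7 gene means in leukemic cells, and couples a
  subset of signature genes to a latent per-cell stemness score.
* ``gen_hto`` lays out Gaussian hashtag clusters on a 2-D embedding with
  rescuable mislabeled Negatives, discardable strays, doublets and background.
* ``gen_survival`` draws exponential survival times whose log-hazard is a
  linear combination of quartile-categorized planted genes.
* ``gen_lda`` draws limiting-dilution engraftment under the single-hit model.

Every generator derives its own random stream from (config.seed, operation
name), so adding a generator never perturbs the others, and identical configs
give byte-identical outputs.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genotyping import MUTANT_CORE, WILDTYPE_CORE, DEFAULT_LOCUS
from .readio import CountMatrix, ReadRecord

#: reference coordinate (1-based) of the first base of the wild-type core
CORE_REF_START = 171_410_536
#: length of the flank sequence on each side of the core in the transcript
FLANK = 144


@dataclass
class SynthConfig:
    """Seeded configuration; defaults define the simulated study conditions."""

    seed: int = 0
    # reads / genotyping
    n_cells: int = 2000
    frac_aml: float = 0.5
    mut_expression_rate: float = 3.0  # mean mutant UMIs per AML cell (Poisson)
    wt_expression_rate: float = 3.0  # mean WT-allele UMIs per cell (Poisson)
    nocall_fraction: float = 0.1  # cells with zero reads over the region
    read_length: int = 90
    # counts
    n_genes: int = 2000
    n_chr7_genes: int = 100
    monosomy_factor: float = 0.5
    n_signature_genes: int = 200
    n_informative: int = 50
    coupling_strength: float = 1.0  # log-mean slope on the latent score
    latent_mean: float = 0.0
    n_clusters: int = 6
    cluster_mix: float = 0.05  # cells assigned across the AML/normal divide
    # survival
    n_patients: int = 300
    n_survival_genes: int = 20
    hazard_coefficients: tuple[float, ...] = (float(np.log(3.0)),)
    censoring_rate: float = 0.3
    # hashtags
    hto_layout: tuple[tuple[str, int, tuple[float, float], float], ...] = (
        ("HTO1", 500, (0.0, 0.0), 1.0),
        ("HTO2", 500, (10.0, 0.0), 1.0),
        ("HTO3", 500, (0.0, 10.0), 1.0),
    )
    hto_negative_fraction: float = 0.05  # in-cluster cells mislabeled Negative
    # false hashtag labels placed far from the cluster; kept below the 2%
    # tail the 0.98-quantile boundary tolerates, else the radius is inflated
    # by the strays themselves
    hto_stray_fraction: float = 0.01
    hto_doublet_fraction: float = 0.05
    hto_background: int = 50
    # limiting dilution
    lda_frequency: float = 1 / 500
    lda_doses: tuple[tuple[int, int], ...] = ((125, 12), (500, 12), (2000, 12))

    def __post_init__(self) -> None:
        for name in (
            "frac_aml",
            "nocall_fraction",
            "censoring_rate",
            "hto_negative_fraction",
            "hto_stray_fraction",
            "hto_doublet_fraction",
            "cluster_mix",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_cells", "n_genes", "n_chr7_genes", "n_signature_genes",
                     "n_patients", "n_survival_genes", "read_length", "n_clusters"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_informative < 0 or self.n_informative > self.n_signature_genes:
            raise ValueError("n_informative must be in [0, n_signature_genes]")
        if self.n_chr7_genes + self.n_signature_genes > self.n_genes:
            raise ValueError("chr7 + signature genes exceed n_genes")
        if self.monosomy_factor <= 0:
            raise ValueError("monosomy_factor must be > 0")
        if self.mut_expression_rate < 0 or self.wt_expression_rate < 0:
            raise ValueError("expression rates must be >= 0")
        if self.lda_frequency < 0:
            raise ValueError("lda_frequency must be >= 0")

    def rng(self, operation: str) -> np.random.Generator:
        """Stream derived from (seed, operation name)."""
        return np.random.default_rng([self.seed, zlib.crc32(operation.encode())])

    def to_dict(self) -> dict:
        return asdict(self)


def _dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _transcripts(config: SynthConfig) -> tuple[str, str, int, int]:
    """(wt transcript, mut transcript, transcript ref start, insertion offset).

    Flanks are fixed by the config seed; the mutant transcript carries the
    duplicated TCTG inserted after the wild-type core's TCTG. The insertion
    offset is the 0-based transcript position where the extra TCTG begins in
    the mutant transcript.
    """
    rng = config.rng("transcript")
    left = _dna(rng, FLANK)
    right = _dna(rng, FLANK)
    wt = left + WILDTYPE_CORE + right
    mut = left + MUTANT_CORE + right
    ref_start = CORE_REF_START - FLANK
    insertion_offset = FLANK + 8  # after GATCTCTG of the core
    return wt, mut, ref_start, insertion_offset


def _project_interval(
    win_start: int, win_end: int, ref_start: int, ins_off: int, mutant: bool
) -> tuple[int, int]:
    """Map a transcript window (0-based inclusive) to 1-based reference coords.

    In the mutant transcript the 4 inserted bases project onto the reference
    position of the last base before the insertion.
    """
    def proj(pos: int) -> int:
        if not mutant or pos < ins_off:
            return ref_start + pos
        if pos < ins_off + 4:  # inside the inserted TCTG
            return ref_start + ins_off - 1
        return ref_start + pos - 4

    return proj(win_start), proj(win_end)


def gen_reads(config: SynthConfig) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Barcoded reads over the mutation locus plus per-cell molecule truth.

    Truth columns: is_aml, n_mut_molecules, n_wt_molecules, nocall (cell
    forced to zero reads). Each molecule is one unique (barcode, UMI) with one
    read placed uniformly along its transcript.
    """
    wt_tx, mut_tx, ref_start, ins_off = _transcripts(config)
    L = config.read_length
    if L <= 0:
        raise ValueError("read_length must be positive")
    if L > len(wt_tx):
        raise ValueError(
            f"read window ({L}) longer than transcript ({len(wt_tx)})"
        )
    rng = config.rng("reads")
    n = config.n_cells
    barcodes = [f"CELL{i:05d}" for i in range(n)]
    is_aml = rng.random(n) < config.frac_aml
    nocall = rng.random(n) < config.nocall_fraction
    n_mut = np.where(
        is_aml & ~nocall, rng.poisson(config.mut_expression_rate, size=n), 0
    )
    n_wt = np.where(~nocall, rng.poisson(config.wt_expression_rate, size=n), 0)

    records: list[ReadRecord] = []
    umi_counter = 0
    for i, bc in enumerate(barcodes):
        for kind, count in (("mut", n_mut[i]), ("wt", n_wt[i])):
            tx = mut_tx if kind == "mut" else wt_tx
            for _ in range(count):
                umi = f"UMI{umi_counter:08d}"
                umi_counter += 1
                start = int(rng.integers(0, len(tx) - L + 1))
                end = start + L - 1
                lo, hi = _project_interval(
                    start, end, ref_start, ins_off, mutant=(kind == "mut")
                )
                records.append(ReadRecord(bc, umi, lo, hi, tx[start : end + 1]))

    truth = pd.DataFrame(
        {
            "is_aml": is_aml,
            "n_mut_molecules": n_mut,
            "n_wt_molecules": n_wt,
            "nocall": nocall,
        },
        index=pd.Index(barcodes, name="cell"),
    )
    return records, truth


def gen_counts(config: SynthConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Clustered negative-binomial count matrix with planted structure.

    Gene layout: genes 0..n_chr7_genes-1 are the chromosome-7 set ("CHR7_*"),
    the next n_signature_genes are the signature set ("SIG_*", first
    n_informative coupled to the latent stemness score), the rest background
    ("GENE_*"). AML cells have chr7 means multiplied by monosomy_factor.

    Truth columns: is_aml, cluster, latent.
    """
    rng = config.rng("counts")
    n_cells, n_genes = config.n_cells, config.n_genes
    n7, nsig, ninf = config.n_chr7_genes, config.n_signature_genes, config.n_informative

    gene_ids = (
        [f"CHR7_{i:04d}" for i in range(n7)]
        + [f"SIG_{i:04d}" for i in range(nsig)]
        + [f"GENE_{i:04d}" for i in range(n_genes - n7 - nsig)]
    )
    cell_ids = [f"CELL{i:05d}" for i in range(n_cells)]

    is_aml = rng.random(n_cells) < config.frac_aml
    latent = rng.normal(config.latent_mean, 1.0, size=n_cells)

    # clusters: AML and normal cells use disjoint cluster pools, with a small
    # mixed fraction crossing over
    half = max(1, config.n_clusters // 2)
    pool_aml = np.arange(half)
    pool_norm = np.arange(half, config.n_clusters)
    if len(pool_norm) == 0:
        pool_norm = pool_aml
    cluster = np.where(
        is_aml,
        rng.choice(pool_aml, size=n_cells),
        rng.choice(pool_norm, size=n_cells),
    )
    crossed = rng.random(n_cells) < config.cluster_mix
    swapped = np.where(
        is_aml, rng.choice(pool_norm, size=n_cells), rng.choice(pool_aml, size=n_cells)
    )
    cluster = np.where(crossed, swapped, cluster)

    base_mean = rng.lognormal(mean=np.log(0.5), sigma=1.0, size=n_genes)
    dispersion = rng.lognormal(mean=np.log(10.0), sigma=0.5, size=n_genes)
    size_factor = rng.lognormal(mean=0.0, sigma=0.2, size=n_cells)

    mean = np.outer(base_mean, size_factor)  # genes x cells
    mean[:n7, is_aml] *= config.monosomy_factor
    if ninf:
        informative = slice(n7, n7 + ninf)
        mean[informative, :] *= np.exp(config.coupling_strength * latent)[None, :]

    # NB via gamma-Poisson: mean m, dispersion theta -> var m + m^2/theta
    lam = rng.gamma(shape=dispersion[:, None], scale=mean / dispersion[:, None])
    counts = rng.poisson(lam)

    meta = pd.DataFrame(
        {
            "cluster": cluster,
            "sample": "S0",
            "timepoint": "T0",
        },
        index=pd.Index(cell_ids, name="cell"),
    )
    matrix = CountMatrix(sp.csr_matrix(counts), gene_ids, cell_ids, meta)
    truth = pd.DataFrame(
        {"is_aml": is_aml, "cluster": cluster, "latent": latent},
        index=pd.Index(cell_ids, name="cell"),
    )
    return matrix, truth


def chr7_genes(config: SynthConfig) -> list[str]:
    return [f"CHR7_{i:04d}" for i in range(config.n_chr7_genes)]


def signature_genes(config: SynthConfig) -> list[str]:
    return [f"SIG_{i:04d}" for i in range(config.n_signature_genes)]


def informative_genes(config: SynthConfig) -> list[str]:
    return [f"SIG_{i:04d}" for i in range(config.n_informative)]


def gen_hto(config: SynthConfig) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """2-D embedding with hashtag-labeled populations plus noise classes.

    Returns (embedding, initial labels, truth). Truth columns: true_label
    (generating hashtag, Negative for background, Doublet), planted
    ('clean' | 'mislabeled_negative' | 'stray' | 'doublet' | 'background').
    """
    if not config.hto_layout:
        raise ValueError("need at least one hashtag population")
    rng = config.rng("hto")
    coords, labels, true_labels, planted = [], [], [], []
    centers = {h: np.asarray(c, dtype=float) for h, _, c, _ in config.hto_layout}
    span = max(10.0, 3 * max(np.abs(c).max() for c in centers.values()))
    for h, n, center, spread in config.hto_layout:
        if spread == 0 and sum(
            np.allclose(center, c) for c in centers.values()
        ) > 1:
            warnings.warn("identical zero-spread hashtag centers overlap")
        pts = rng.normal(loc=center, scale=max(spread, 0.0), size=(n, 2))
        u = rng.random(n)
        for i in range(n):
            coords.append(pts[i])
            true_labels.append(h)
            if u[i] < config.hto_negative_fraction:
                labels.append("Negative")
                planted.append("mislabeled_negative")
            elif u[i] < config.hto_negative_fraction + config.hto_stray_fraction:
                # labeled with the hashtag but placed far from its cluster
                coords[-1] = center + rng.uniform(15, 25, 2) * rng.choice([-1.0, 1.0], 2)
                labels.append(h)
                planted.append("stray")
            else:
                labels.append(h)
                planted.append("clean")
    n_real = len(coords)
    n_doublet = int(round(config.hto_doublet_fraction * n_real))
    for _ in range(n_doublet):
        coords.append(rng.uniform(-span, span, 2))
        labels.append("Doublet")
        true_labels.append("Doublet")
        planted.append("doublet")
    for _ in range(config.hto_background):
        coords.append(rng.uniform(-span, span, 2))
        labels.append("Negative")
        true_labels.append("Negative")
        planted.append("background")
    embedding = np.asarray(coords)
    truth = pd.DataFrame({"true_label": true_labels, "planted": planted})
    return embedding, np.asarray(labels, dtype=object), truth


def gen_survival(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patients x genes expression plus a survival table (time, event).

    Expression is standard normal; the log-hazard is hazard_coefficients
    applied to the quartile-categorized values of the first planted genes;
    times are exponential with independent exponential censoring calibrated
    to ``censoring_rate``.
    """
    rng = config.rng("survival")
    n, g = config.n_patients, config.n_survival_genes
    genes = [f"SURV_{i:03d}" for i in range(g)]
    patients = [f"PT{i:04d}" for i in range(n)]
    expr = pd.DataFrame(
        rng.normal(size=(n, g)), index=pd.Index(patients, name="patient"), columns=genes
    )

    beta = np.zeros(g)
    k = min(len(config.hazard_coefficients), g)
    beta[:k] = config.hazard_coefficients[:k]
    q1 = np.quantile(expr.to_numpy(), 0.25, axis=1)
    q3 = np.quantile(expr.to_numpy(), 0.75, axis=1)
    cat = np.zeros((n, g))
    cat[expr.to_numpy() < q1[:, None]] = -1
    cat[expr.to_numpy() > q3[:, None]] = 1
    lp = cat @ beta

    base_rate = 0.1
    rate = base_rate * np.exp(lp)
    event_time = rng.exponential(1.0 / rate)
    if config.censoring_rate >= 1.0:
        time = rng.exponential(1.0 / base_rate, size=n)
        event = np.zeros(n, dtype=int)
    elif config.censoring_rate <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        c_rate = config.censoring_rate / (1 - config.censoring_rate) * rate.mean()
        censor_time = rng.exponential(1.0 / c_rate, size=n)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    surv = pd.DataFrame(
        {"time": time, "event": event}, index=pd.Index(patients, name="patient")
    )
    return expr, surv


def gen_lda(config: SynthConfig) -> pd.DataFrame:
    """Dose/engraftment table under the single-hit model.

    Each mouse engrafts with probability 1 - exp(-f * dose); returns columns
    dose, n_tested, n_negative.
    """
    rng = config.rng("lda")
    rows = []
    for dose, n_mice in config.lda_doses:
        p_engraft = 1.0 - np.exp(-config.lda_frequency * dose)
        engrafted = int(rng.binomial(n_mice, p_engraft))
        rows.append({"dose": dose, "n_tested": n_mice, "n_negative": n_mice - engrafted})
    return pd.DataFrame(rows)
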