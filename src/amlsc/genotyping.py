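"""Single-cell NPM1 type-A mutation genotyping from 3' reads.

The NPM1 type-A mutation is a 4-nt TCTG tandem duplication near the 3' end of
NPM1 (chr5:171410540-171410543), close enough to the polyadenylation site to be
captured by 3' scRNA-seq reads. A cell carrying a single mutant transcript is
leukemic; the converse does not hold, so wild-type classification demands
stronger evidence (>5 wild-type transcripts and none mutant).

The matcher searches each read for the duplication-bearing core and for its
boundary truncations: one unanchored motif that fits entirely inside a read,
four suffix-anchored motifs (duplication runs off the 3' read end) and five
prefix-anchored motifs (duplication starts before the read). Matching is exact;
a single mismatch voids the motif, so sequencing errors cost sensitivity but
never specificity.

Per-cell calls feed a sequential cluster-level assignment: leukemic cells
co-cluster, so clusters with enough MUT cells (and few enough WT cells) are
extended wholesale to leukemic, while low-MUT clusters contribute only their
individually genotyped MUT cells.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .readio import ReadRecord

#: duplication-bearing mutant core and its wild-type counterpart (TCTG removed)
MUTANT_CORE = "GATCTCTGTCTGGCAG"
WILDTYPE_CORE = "GATCTCTGGCAG"

#: 1-based inclusive reference interval of the duplicated TCTG
DEFAULT_LOCUS = (171_410_540, 171_410_543)


@dataclass(frozen=True)
class PatternSet:
    """Mutant-supporting motifs split by anchoring.

    ``unanchored`` motifs may occur anywhere in a read; ``suffix_anchored``
    motifs must end the read (duplication truncated at the 3' boundary);
    ``prefix_anchored`` motifs must begin the read.
    """

    unanchored: tuple[str, ...]
    suffix_anchored: tuple[str, ...]
    prefix_anchored: tuple[str, ...]
    locus: tuple[int, int] = DEFAULT_LOCUS

    def __post_init__(self) -> None:
        for motif in self.all_motifs():
            if not motif or set(motif) - set("ACGT"):
                raise ValueError(f"motif {motif!r} is not a non-empty ACGT string")

    def all_motifs(self) -> tuple[str, ...]:
        return self.unanchored + self.suffix_anchored + self.prefix_anchored


#: default motif set for the NPM1 type-A duplication
NPM1_TYPE_A = PatternSet(
    unanchored=("TCTCTGTCTGGC",),
    suffix_anchored=("GATCTCTGTCTGG", "GATCTCTGTCTG", "GATCTCTGTCT", "GATCTCTGTC"),
    prefix_anchored=(
        "CTCTGTCTGGCAG",
        "TCTGTCTGGCAG",
        "CTGTCTGGCAG",
        "TGTCTGGCAG",
        "GTCTGGCAG",
    ),
)


@dataclass(frozen=True)
class MoleculeCall:
    """Allele call for one UMI (one captured transcript molecule)."""

    cell_barcode: str
    umi: str
    allele: str  # MUT | WT | uninformative
    n_reads: int


@dataclass(frozen=True)
class CellGenotype:
    cell_barcode: str
    n_mut_umi: int
    n_wt_umi: int
    has_coverage: bool
    call: str  # MUT | WT | ND | NoCall


@dataclass
class ClusterAssignment:
    cluster: object
    n_cells: int
    frac_mut: float
    frac_wt: float
    frac_nd: float
    frac_nocall: float
    myeloid: bool
    criterion_fired: int
    fallback: bool
    aml_cell_ids: list[str] = field(default_factory=list)


def match_read(sequence: str, patterns: PatternSet = NPM1_TYPE_A) -> bool:
    """True iff the read supports the mutant allele.

    Non-ACGT characters never match (exact matching), with a one-shot warning.
    """
    if set(sequence) - set("ACGT"):
        warnings.warn(
            "read sequence contains non-ACGT characters; they never match",
            stacklevel=2,
        )
    return (
        any(m in sequence for m in patterns.unanchored)
        or any(sequence.endswith(m) for m in patterns.suffix_anchored)
        or any(sequence.startswith(m) for m in patterns.prefix_anchored)
    )


def collapse_molecules(
    reads: Iterable[ReadRecord], patterns: PatternSet = NPM1_TYPE_A
) -> list[MoleculeCall]:
    """Collapse reads to one allele call per (cell barcode, UMI).

    A molecule is MUT if any of its reads matches a mutant motif (a single
    mutant transcript is enough); otherwise WT if some read's aligned interval
    fully contains the duplication locus (absence of the duplication is only
    informative when the full locus was sequenced); otherwise uninformative.
    """
    lo, hi = patterns.locus
    state: dict[tuple[str, str], list] = {}
    order: list[tuple[str, str]] = []
    for read in reads:
        key = (read.cell_barcode, read.umi)
        if key not in state:
            state[key] = [False, False, 0]  # has_mut, has_wt_containment, n_reads
            order.append(key)
        s = state[key]
        s[2] += 1
        if match_read(read.sequence, patterns):
            s[0] = True
        elif read.ref_start <= lo and read.ref_end >= hi:
            s[1] = True
    calls = []
    for bc, umi in order:
        has_mut, has_wt, n = state[(bc, umi)]
        allele = "MUT" if has_mut else ("WT" if has_wt else "uninformative")
        calls.append(MoleculeCall(bc, umi, allele, n))
    return calls


def compute_coverage(
    reads: Iterable[ReadRecord], locus: tuple[int, int] = DEFAULT_LOCUS
) -> dict[str, bool]:
    """Per-cell flag: any read overlapping the locus interval by >= 1 base."""
    lo, hi = locus
    cov: dict[str, bool] = {}
    for read in reads:
        overlaps = read.ref_start <= hi and read.ref_end >= lo
        cov[read.cell_barcode] = cov.get(read.cell_barcode, False) or overlaps
    return cov


def genotype_cells(
    molecules: Iterable[MoleculeCall], coverage: Mapping[str, bool]
) -> list[CellGenotype]:
    """Classify each cell as MUT / WT / ND / NoCall from its molecule calls.

    MUT: >= 1 mutant UMI. WT: no mutant UMI and > 5 WT UMIs. ND (not
    detected): no mutant UMI, <= 5 WT UMIs, but locus coverage exists.
    NoCall: no read over the mutation region at all. Every cell in
    ``coverage`` receives exactly one class.
    """
    counts: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    for mol in molecules:
        if mol.allele == "MUT":
            counts[mol.cell_barcode][0] += 1
        elif mol.allele == "WT":
            counts[mol.cell_barcode][1] += 1
        else:
            counts[mol.cell_barcode]  # touch: cell has molecules
    genotypes = []
    cells = list(coverage.keys())
    for bc in counts:
        if bc not in coverage:
            cells.append(bc)
    for bc in cells:
        has_cov = bool(coverage.get(bc, False))
        n_mut, n_wt = counts.get(bc, (0, 0))
        # uninformative molecules (reads off the locus) are consistent with
        # missing coverage; classified ones are not
        if (n_mut or n_wt) and not has_cov:
            raise ValueError(
                f"cell {bc!r} has classified molecules but no locus coverage"
            )
        if not has_cov:
            call = "NoCall"
        elif n_mut >= 1:
            call = "MUT"
        elif n_wt > 5:
            call = "WT"
        else:
            call = "ND"
        genotypes.append(CellGenotype(bc, n_mut, n_wt, has_cov, call))
    return genotypes


def assign_clusters(
    genotypes: Iterable[CellGenotype],
    clusters: Mapping[str, object],
    myeloid: Mapping[object, bool] | None = None,
    denominator: str = "all",
) -> tuple[list[ClusterAssignment], dict[str, bool]]:
    """Cluster-level leukemia assignment by sequential criteria.

    Evaluated strictly in order on each cluster's class fractions:

    1. MUT >= 40%: extend to whole cluster.
    2. 20% <= MUT < 40% and WT < 5%: extend to whole cluster.
    3. 10% <= MUT < 20% and WT < 5%, myeloid cluster, majority NoCall: extend.
    4. 5% <= MUT < 10% and WT = 0%, myeloid cluster, majority NoCall: extend.
    5. MUT < 5%: only MUT cells are leukemic.

    Configurations matching no criterion (e.g. MUT 25%, WT 6%) fall back to
    criterion-5 behavior (only MUT cells), flagged via ``fallback``. Whole-
    cluster extension marks every non-WT cell leukemic; WT cells are excluded
    everywhere. Fractions use all cluster cells by default
    (``denominator='covered'`` restricts to cells with locus coverage).

    Returns per-cluster assignments and a per-cell leukemic flag.
    """
    if denominator not in ("all", "covered"):
        raise ValueError(f"unknown denominator {denominator!r}")
    myeloid = myeloid or {}
    by_cluster: dict[object, list[CellGenotype]] = defaultdict(list)
    for g in genotypes:
        if g.cell_barcode not in clusters:
            raise ValueError(f"cell {g.cell_barcode!r} has no cluster label")
        by_cluster[clusters[g.cell_barcode]].append(g)

    assignments = []
    aml: dict[str, bool] = {}
    for cluster, members in by_cluster.items():
        if not members:
            warnings.warn(f"cluster {cluster!r} is empty; skipped")
            continue
        denom = [m for m in members if m.has_coverage] if denominator == "covered" else members
        n = len(denom)
        if n == 0:
            warnings.warn(f"cluster {cluster!r} has no covered cells; skipped")
            continue
        frac = {
            c: sum(m.call == c for m in denom) / n for c in ("MUT", "WT", "ND", "NoCall")
        }
        is_myeloid = bool(myeloid.get(cluster, False))
        f_mut, f_wt, f_nocall = frac["MUT"], frac["WT"], frac["NoCall"]
        fallback = False
        if f_mut >= 0.40:
            crit, whole = 1, True
        elif 0.20 <= f_mut < 0.40 and f_wt < 0.05:
            crit, whole = 2, True
        elif 0.10 <= f_mut < 0.20 and f_wt < 0.05 and is_myeloid and f_nocall > 0.5:
            crit, whole = 3, True
        elif 0.05 <= f_mut < 0.10 and f_wt == 0.0 and is_myeloid and f_nocall > 0.5:
            crit, whole = 4, True
        elif f_mut < 0.05:
            crit, whole = 5, False
        else:
            crit, whole, fallback = 5, False, True
        if whole:
            aml_ids = [m.cell_barcode for m in members if m.call != "WT"]
        else:
            aml_ids = [m.cell_barcode for m in members if m.call == "MUT"]
        for m in members:
            aml[m.cell_barcode] = False
        for bc in aml_ids:
            aml[bc] = True
        assignments.append(
            ClusterAssignment(
                cluster=cluster,
                n_cells=len(members),
                frac_mut=f_mut,
                frac_wt=f_wt,
                frac_nd=frac["ND"],
                frac_nocall=f_nocall,
                myeloid=is_myeloid,
                criterion_fired=crit,
                fallback=fallback,
                aml_cell_ids=aml_ids,
            )
        )
    return assignments, aml
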