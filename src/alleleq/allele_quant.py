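"""Allele-resolved quantification of endogenous vs. exogenous transcripts.

The endogenous gene and the delivered replacement construct differ only at
the recoded RNAi target site, so reads spanning that site identify the
allele of origin.  Counting is deliberately strict: a read is assigned to an
allele iff the full-length site sequence (or its reverse complement) occurs
as an exact substring.  Reads matching neither allele — sequencing errors,
reads not spanning the site — are ignored; the rare read matching both is
counted as neither and logged.

Group-level allele fractions are pooled over all cells with at least one
site-spanning read, then applied to each cell's depth-normalised expression
(counts per million) to split it into endogenous and exogenous components.
Knockdown efficiency compares the mean endogenous expression of a treated
group with the mean total expression of an untreated control group (assumed
fully endogenous).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .construct_design import _clean, hamming, reverse_complement

logger = logging.getLogger(__name__)

__all__ = [
    "QuantError",
    "SiteSignature",
    "AlleleCounts",
    "CellRecord",
    "GroupEstimates",
    "count_allele_reads",
    "pooled_allele_fraction",
    "normalize_expression",
    "allocate_allele_expression",
    "knockdown_efficiency",
    "summarize_group",
]


class QuantError(ValueError):
    """Raised on invalid quantification inputs."""


_MATE_SUFFIX = re.compile(r"(/[12]|[_ ][12])$")


@dataclass(frozen=True)
class SiteSignature:
    """The paired site sequences that define allele identity.

    Holds the endogenous and exogenous site in the orientation they appear
    on the transcript, plus both reverse complements (reads may come from
    either strand).
    """

    endo_site: str
    exo_site: str

    def __post_init__(self) -> None:
        endo = _clean(self.endo_site, allow_n=False)
        exo = _clean(self.exo_site, allow_n=False)
        object.__setattr__(self, "endo_site", endo)
        object.__setattr__(self, "exo_site", exo)
        if len(endo) != len(exo):
            raise QuantError("site sequences must have equal length")
        if hamming(endo, exo) < 1:
            raise QuantError("sites must differ at >=1 position")
        for a, b in ((endo, exo), (exo, endo)):
            if any(a in s for s in (b, reverse_complement(b))):
                raise QuantError("one site is contained in the other's orientation set")

    @property
    def endo_variants(self) -> tuple[str, str]:
        return self.endo_site, reverse_complement(self.endo_site)

    @property
    def exo_variants(self) -> tuple[str, str]:
        return self.exo_site, reverse_complement(self.exo_site)

    @property
    def site_length(self) -> int:
        return len(self.endo_site)


@dataclass
class AlleleCounts:
    cell_id: str
    n_endo: int = 0
    n_exo: int = 0

    @property
    def n_site_reads(self) -> int:
        return self.n_endo + self.n_exo


@dataclass
class CellRecord:
    """Per-cell QC metrics and expression of the gene of interest."""

    cell_id: str
    group: str
    total_mapped_reads: int
    tmc1_raw_count: int

    @property
    def tmc1_expression(self) -> float:
        """Depth-normalised expression in counts per million (CPM)."""
        return normalize_expression(self.tmc1_raw_count, self.total_mapped_reads)


@dataclass
class GroupEstimates:
    group: str
    pct_endo: float
    pct_exo: float
    n_cells_used: int
    cell_ids: list[str]
    tmc1_expression: list[float]
    endo_expression: list[float]
    exo_expression: list[float]
    knockdown_efficiency: float | None = None


def _matches(read: str, variants: tuple[str, str]) -> bool:
    return variants[0] in read or variants[1] in read


def count_allele_reads(
    reads: Iterable, signature: SiteSignature, cell_id: str = ""
) -> AlleleCounts:
    """Count fragments carrying an exact endogenous or exogenous site.

    ``reads`` yields ``(read_id, bases)`` pairs or objects with ``id`` and
    ``seq`` attributes (e.g. Bio.SeqRecord).  Mates sharing a read id (after
    stripping ``/1``-style suffixes) are collapsed to one fragment; a
    fragment matching in either mate counts once.  A fragment matching both
    alleles is counted as neither and logged.
    """
    frag_endo: dict[str, bool] = {}
    frag_exo: dict[str, bool] = {}
    order: list[str] = []
    for read in reads:
        if isinstance(read, tuple):
            rid, bases = read
        else:
            rid, bases = read.id, str(read.seq)
        rid = _MATE_SUFFIX.sub("", str(rid))
        bases = str(bases).upper()
        if rid not in frag_endo:
            frag_endo[rid] = False
            frag_exo[rid] = False
            order.append(rid)
        if _matches(bases, signature.endo_variants):
            frag_endo[rid] = True
        if _matches(bases, signature.exo_variants):
            frag_exo[rid] = True
    n_endo = n_exo = 0
    for rid in order:
        e, x = frag_endo[rid], frag_exo[rid]
        if e and x:
            logger.warning("fragment %s matches both alleles; counted as neither", rid)
        elif e:
            n_endo += 1
        elif x:
            n_exo += 1
    return AlleleCounts(cell_id=cell_id, n_endo=n_endo, n_exo=n_exo)


def pooled_allele_fraction(
    counts: Sequence[AlleleCounts],
) -> tuple[float, float, int]:
    """Pool site-read counts over cells into group allele percentages.

    Cells without site-spanning reads are excluded; percentages are computed
    from the summed counts of the remaining cells and sum to 100.
    """
    if not counts:
        raise QuantError("no cells supplied")
    used = [c for c in counts if c.n_site_reads > 0]
    if not used:
        raise QuantError("no cell has site-spanning reads; allele fraction undefined")
    endo = sum(c.n_endo for c in used)
    exo = sum(c.n_exo for c in used)
    total = endo + exo
    return 100.0 * endo / total, 100.0 * exo / total, len(used)


def normalize_expression(raw_count: float, total_mapped_reads: int) -> float:
    """Counts-per-million depth normalisation."""
    if total_mapped_reads <= 0:
        raise QuantError("total_mapped_reads must be positive")
    if raw_count < 0:
        raise QuantError("negative count")
    return raw_count / total_mapped_reads * 1e6


def allocate_allele_expression(
    tmc1_expression: float, pct_endo: float, pct_exo: float
) -> tuple[float, float]:
    """Split a cell's expression into allele components by group fractions.

    The exogenous component is ``expression * pct_exo / 100`` and the
    endogenous component is the exact remainder, so the two always sum to
    the input expression.
    """
    if tmc1_expression < 0:
        raise QuantError("negative expression")
    if abs(pct_endo + pct_exo - 100.0) > 1e-6:
        raise QuantError("fractions must sum to 100")
    exo = tmc1_expression * pct_exo / 100.0
    endo = tmc1_expression - exo
    # re-subtract so endo + exo reproduces the input bit-for-bit
    exo = tmc1_expression - endo
    return endo, exo


def knockdown_efficiency(
    treated_endo_expression: Sequence[float],
    control_expression: Sequence[float],
) -> float:
    """Endogenous-allele knockdown as a percentage.

    ``100 * (1 - mean(treated endogenous expression) / mean(control total
    expression))``; the control group is assumed fully endogenous.  A
    negative value (treated endogenous above control) is returned as-is and
    logged.
    """
    if len(treated_endo_expression) == 0 or len(control_expression) == 0:
        raise QuantError("both groups must be non-empty")
    control_mean = sum(control_expression) / len(control_expression)
    if control_mean == 0:
        raise QuantError("control mean expression is zero")
    treated_mean = sum(treated_endo_expression) / len(treated_endo_expression)
    kd = 100.0 * (1.0 - treated_mean / control_mean)
    if kd < 0:
        logger.warning("treated endogenous expression exceeds control (knockdown %.1f%%)", kd)
    return kd


def summarize_group(
    group: str,
    cells: Sequence[CellRecord],
    counts: Sequence[AlleleCounts],
    control_expression: Sequence[float] | None = None,
) -> GroupEstimates:
    """Assemble per-group allele estimates from cells and site-read counts.

    Pools allele fractions across the group, allocates each cell's CPM to
    alleles, and, when a control group's expression vector is supplied,
    estimates knockdown efficiency of the endogenous allele.
    """
    pct_endo, pct_exo, n_used = pooled_allele_fraction(list(counts))
    expr = [c.tmc1_expression for c in cells]
    endo_expr, exo_expr = [], []
    for e in expr:
        en, ex = allocate_allele_expression(e, pct_endo, pct_exo)
        endo_expr.append(en)
        exo_expr.append(ex)
    kd = None
    if control_expression is not None:
        kd = knockdown_efficiency(endo_expr, control_expression)
    return GroupEstimates(
        group=group,
        pct_endo=pct_endo,
        pct_exo=pct_exo,
        n_cells_used=n_used,
        cell_ids=[c.cell_id for c in cells],
        tmc1_expression=expr,
        endo_expression=endo_expr,
        exo_expression=exo_expr,
        knockdown_efficiency=kd,
    )
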