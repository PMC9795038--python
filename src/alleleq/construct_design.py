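"""Design of knockdown-resistant, synonymously recoded RNAi target sites.

An RNAi guide silences any transcript carrying an exact (or near-exact) copy
of its target site.  A replacement cDNA can escape that silencing if the
site is rewritten with synonymous codons: the encoded protein is unchanged
while the nucleotide sequence diverges from the guide.  This module provides
the primitives for that design task:

* frame/orientation inference that proves (or refutes) synonymy of a given
  site pair, searching all three frame offsets in both strand orientations;
* a recoding engine that, for each codon fully contained in the target site,
  picks the synonymous codon with the most nucleotide changes (ties broken
  by the lexicographically smallest codon, so output is deterministic);
* a resistance check against total- and seed-region mismatch thresholds;
* a sliding-window scan ranking candidate sites of a CDS by how many
  mismatches synonymous recoding can buy.

Coordinates are 0-based, half-open throughout.  Codons that straddle a site
edge, contain a stop, or contain an ambiguous base are never edited.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

__all__ = [
    "DesignError",
    "CodingContext",
    "FrameResult",
    "RecodedSite",
    "reverse_complement",
    "hamming",
    "translate",
    "infer_matching_frame",
    "recode_site",
    "verify_resistance",
    "enumerate_candidate_sites",
]

_ALPHABET = set("ACGTN")
_STOPS = set(standard_dna_table.stop_codons)

# codon -> amino acid (stops as '*'), and amino acid -> synonymous codons
_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in _STOPS})
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(_CODON_TO_AA.items()):
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)


class DesignError(ValueError):
    """Raised on invalid design inputs (alphabet, lengths, intervals)."""


def _clean(seq: str, *, allow_n: bool = True) -> str:
    s = str(seq).upper().replace("U", "T")
    allowed = _ALPHABET if allow_n else _ALPHABET - {"N"}
    bad = set(s) - allowed
    if bad:
        raise DesignError(f"invalid nucleotide character(s): {sorted(bad)}")
    if not s:
        raise DesignError("empty sequence")
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    return str(Seq(_clean(seq)).reverse_complement())


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length sequences."""
    a, b = _clean(a), _clean(b)
    if len(a) != len(b):
        raise DesignError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def translate(seq: str, frame_offset: int = 0) -> str:
    """Translate complete codons of ``seq`` starting at ``frame_offset``.

    Stops render as ``*``; any codon containing a base outside {A,C,G,T}
    renders as ``X``.  Trailing bases short of a codon are dropped.
    """
    seq = _clean(seq)
    if frame_offset not in (0, 1, 2):
        raise DesignError("frame_offset must be 0, 1 or 2")
    if len(seq) - frame_offset < 3:
        raise DesignError("fewer than one complete codon in this frame")
    out = []
    for i in range(frame_offset, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        out.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(out)


@dataclass(frozen=True)
class FrameResult:
    """Outcome of joint frame/orientation inference on a site pair."""

    orientation: str          # "sense" | "antisense"
    frame_offset: int         # 0 | 1 | 2, in the chosen orientation
    synonymous: bool
    diff_positions: list[int]            # 0-based, oriented coordinates
    codon_position_of_diffs: list[int]   # 1..3 within the inferred frame
    peptide_a: str
    peptide_b: str
    n_matching_aa: int

    @property
    def n_diffs(self) -> int:
        return len(self.diff_positions)


def infer_matching_frame(site_a: str, site_b: str) -> FrameResult:
    """Find the frame/orientation in which two sites are synonymous.

    Both sites are examined jointly in all 3 frame offsets x 2 orientations
    (antisense reverse-complements *both* sequences).  The first candidate
    with identical peptides wins; otherwise the candidate with the most
    matching amino acids is returned with ``synonymous=False``.
    """
    a, b = _clean(site_a), _clean(site_b)
    if len(a) != len(b):
        raise DesignError("sites must have equal length")
    if len(a) < 3:
        raise DesignError("sites must be at least one codon long")

    best: FrameResult | None = None
    for orientation in ("sense", "antisense"):
        if orientation == "sense":
            oa, ob = a, b
        else:
            oa, ob = reverse_complement(a), reverse_complement(b)
        for off in range(3):
            if len(a) - off < 3:
                continue
            pa, pb = translate(oa, off), translate(ob, off)
            diffs = [i for i, (x, y) in enumerate(zip(oa, ob)) if x != y]
            # a diff outside the fully-covered codons escapes the peptide
            # comparison, so it cannot count as proven-synonymous
            last = off + 3 * len(pa)
            covered = all(off <= p < last for p in diffs)
            cand = FrameResult(
                orientation=orientation,
                frame_offset=off,
                synonymous=(pa == pb and covered),
                diff_positions=diffs,
                codon_position_of_diffs=[((p - off) % 3) + 1 for p in diffs],
                peptide_a=pa,
                peptide_b=pb,
                n_matching_aa=sum(x == y for x, y in zip(pa, pb)),
            )
            if cand.synonymous:
                return cand
            if best is None or cand.n_matching_aa > best.n_matching_aa:
                best = cand
    assert best is not None
    return best


@dataclass(frozen=True)
class CodingContext:
    """A CDS with a declared target-site interval, frame and orientation.

    ``frame_offset`` is the index (0/1/2) of the first base of a complete
    codon in the *oriented* CDS; ``orientation="antisense"`` means the codon
    grid lives on the reverse complement of ``cds``.
    """

    cds: str
    site_start: int
    site_length: int = 21
    frame_offset: int = 0
    orientation: str = "sense"

    def __post_init__(self) -> None:
        object.__setattr__(self, "cds", _clean(self.cds))
        if self.orientation not in ("sense", "antisense"):
            raise DesignError("orientation must be 'sense' or 'antisense'")
        if self.frame_offset not in (0, 1, 2):
            raise DesignError("frame_offset must be 0, 1 or 2")
        if self.site_length <= 0:
            raise DesignError("site_length must be positive")
        if not (0 <= self.site_start and self.site_start + self.site_length <= len(self.cds)):
            raise DesignError("site interval outside CDS")

    @property
    def site(self) -> str:
        return self.cds[self.site_start : self.site_start + self.site_length]


@dataclass(frozen=True)
class RecodedSite:
    """An engineered site together with its synonymy proof."""

    original: str
    engineered: str
    n_substitutions: int
    substitution_positions: list[int]       # 0-based within the site, input orientation
    synonymy_verified: bool
    per_codon_substitutions: list[int] = field(default_factory=list)
    stop_codons_preserved: int = 0
    engineered_cds: str = ""

    def __post_init__(self) -> None:
        if len(self.original) != len(self.engineered):
            raise DesignError("original and engineered sites differ in length")
        if self.n_substitutions != hamming(self.original, self.engineered):
            raise DesignError("n_substitutions inconsistent with sequences")


def _max_divergent_synonymous(codon: str) -> tuple[str, int]:
    """Synonymous codon with the most mismatches to ``codon`` (ties: smallest)."""
    aa = _CODON_TO_AA.get(codon)
    if aa is None or aa == "*":
        return codon, 0
    best_codon, best_score = codon, 0
    for cand in _AA_TO_CODONS[aa]:  # sorted lexicographically
        score = sum(x != y for x, y in zip(cand, codon))
        if score > best_score:
            best_codon, best_score = cand, score
    return best_codon, best_score


def recode_site(
    ctx: CodingContext,
    forbid_original_kmers: bool = False,
    engineered: str | None = None,
) -> RecodedSite:
    """Produce a maximally divergent synonymous version of the target site.

    Every codon of the declared frame that lies entirely inside the site is
    replaced by the synonymous codon with the most nucleotide mismatches
    (deterministic: ties go to the lexicographically smallest codon).  Codons
    straddling a site edge, stop codons, and codons with ambiguous bases are
    preserved verbatim.  Since codons are disjoint, per-codon maximisation is
    globally optimal.

    With ``engineered`` given, that site replaces the optimiser's output
    ("match a provided engineered sequence" mode); synonymy in the declared
    frame is verified and a non-synonymous sequence is rejected.

    ``forbid_original_kmers=True`` rejects designs in which the engineered
    CDS still contains the original site (or its reverse complement), i.e.
    designs that would remain visible to the guide.
    """
    # work on the oriented CDS so the codon grid is explicit
    if ctx.orientation == "antisense":
        o_cds = reverse_complement(ctx.cds)
        o_start = len(ctx.cds) - (ctx.site_start + ctx.site_length)
    else:
        o_cds = ctx.cds
        o_start = ctx.site_start
    o_end = o_start + ctx.site_length

    if engineered is not None:
        engineered = _clean(engineered)
        if len(engineered) != ctx.site_length:
            raise DesignError("engineered site length differs from site interval")
        o_site_new = (
            reverse_complement(engineered) if ctx.orientation == "antisense" else engineered
        )
        new_cds = o_cds[:o_start] + o_site_new + o_cds[o_end:]
        per_codon: list[int] = []
        n_stops = 0
    else:
        chars = list(o_cds)
        per_codon = []
        n_stops = 0
        first = ctx.frame_offset + 3 * ((o_start - ctx.frame_offset + 2) // 3)
        first = max(first, ctx.frame_offset)
        any_complete = False
        for cstart in range(first, o_end - 2, 3):
            if cstart < o_start:
                continue
            any_complete = True
            codon = o_cds[cstart : cstart + 3]
            if codon in _STOPS:
                n_stops += 1
                per_codon.append(0)
                continue
            new_codon, score = _max_divergent_synonymous(codon)
            chars[cstart : cstart + 3] = new_codon
            per_codon.append(score)
        if not any_complete:
            raise DesignError("site does not cover a complete codon in this frame")
        new_cds = "".join(chars)
        o_site_new = new_cds[o_start:o_end]

    # synonymy proof over the complete codons of the oriented CDS
    ok = translate(o_cds, ctx.frame_offset) == translate(new_cds, ctx.frame_offset)
    if engineered is not None and not ok:
        raise DesignError("provided engineered site is not synonymous in the declared frame")

    # map back into the input orientation
    if ctx.orientation == "antisense":
        site_new = reverse_complement(o_site_new)
        cds_new = reverse_complement(new_cds)
    else:
        site_new = o_site_new
        cds_new = new_cds
    original_site = ctx.site
    subs = [i for i, (x, y) in enumerate(zip(original_site, site_new)) if x != y]

    if forbid_original_kmers:
        if original_site in cds_new or reverse_complement(original_site) in cds_new:
            raise DesignError("engineered CDS still contains the original target site")

    return RecodedSite(
        original=original_site,
        engineered=site_new,
        n_substitutions=len(subs),
        substitution_positions=subs,
        synonymy_verified=ok,
        per_codon_substitutions=per_codon,
        stop_codons_preserved=n_stops,
        engineered_cds=cds_new,
    )


def verify_resistance(
    recoded: RecodedSite,
    min_total_mismatches: int = 6,
    min_seed_mismatches: int = 1,
    seed_interval: tuple[int, int] = (1, 8),
) -> tuple[bool, dict]:
    """Check that a recoded site clears mismatch thresholds.

    ``seed_interval`` is a 0-based half-open window within the site (default
    positions 1-7, the guide seed-pairing region, which dominates RNAi
    recognition).  Returns ``(passed, report)``; the report lists total and
    seed mismatch positions.
    """
    lo, hi = seed_interval
    if not (0 <= lo < hi <= len(recoded.original)):
        raise DesignError("seed interval outside site")
    positions = recoded.substitution_positions
    seed_hits = [p for p in positions if lo <= p < hi]
    passed = len(positions) >= min_total_mismatches and len(seed_hits) >= min_seed_mismatches
    report = {
        "n_total_mismatches": len(positions),
        "mismatch_positions": list(positions),
        "n_seed_mismatches": len(seed_hits),
        "seed_mismatch_positions": seed_hits,
        "seed_interval": [lo, hi],
        "min_total_mismatches": min_total_mismatches,
        "min_seed_mismatches": min_seed_mismatches,
        "passed": passed,
    }
    return passed, report


def enumerate_candidate_sites(
    cds: str, site_length: int = 21, frame_offset: int = 0
) -> list[tuple[int, str, int]]:
    """Rank every sliding window of ``cds`` by recodable mismatches.

    Returns ``(offset, site, max_recodable_mismatches)`` records sorted by
    score descending, ties by offset ascending.  The score is what the
    recoding engine can achieve for that window on the CDS codon grid.
    """
    cds = _clean(cds)
    if len(cds) < site_length:
        raise DesignError("CDS shorter than site length")
    records = []
    for off in range(len(cds) - site_length + 1):
        ctx = CodingContext(
            cds=cds, site_start=off, site_length=site_length, frame_offset=frame_offset
        )
        try:
            score = recode_site(ctx).n_substitutions
        except DesignError:  # window without a complete codon
            score = 0
        records.append((off, cds[off : off + site_length], score))
    records.sort(key=lambda r: (-r[2], r[0]))
    return records


def brute_force_recode_score(site: str, frame_offset: int = 0) -> int:
    """Exhaustive synonymous-maximisation oracle for small sites (<=7 codons).

    Enumerates every combination of synonymous codons over the complete
    codons of ``site`` and returns the maximal total mismatch count.  Used
    for testing the greedy engine; exponential, keep sites short.
    """
    site = _clean(site)
    codons = [
        site[i : i + 3]
        for i in range(frame_offset, len(site) - 2, 3)
    ]
    choices = []
    for codon in codons:
        aa = _CODON_TO_AA.get(codon)
        if aa is None or aa == "*":
            choices.append([codon])
        else:
            choices.append(_AA_TO_CODONS[aa])
    best = 0
    for combo in itertools.product(*choices):
        score = sum(
            x != y for codon, new in zip(codons, combo) for x, y in zip(codon, new)
        )
        best = max(best, score)
    return best
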