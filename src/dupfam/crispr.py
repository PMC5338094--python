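"""CRISPR amplicon indel calling and spacer-site scanning.

Replaces visual counting of frameshift reads at a Cas9 cut site with an
algorithmic pipeline: global alignment of each amplicon read to the
reference, net indel length within a window around the cut site, and
classification into unedited / in-frame / frameshift. A clone is called
"high" when its frameshift read fraction reaches a configured threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .io_formats import SequenceRecord, reverse_complement

__all__ = [
    "AmpliconConfig",
    "SpacerSite",
    "PairwiseAlignment",
    "IndelCall",
    "CloneSummary",
    "find_spacer_sites",
    "align_read",
    "call_indel",
    "summarize_clone",
]


@dataclass
class AmpliconConfig:
    """Reference amplicon, cut-site offset (0-based) and calling window."""

    reference: SequenceRecord
    cut_site: int
    window: int = 20
    frameshift_threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.cut_site < len(self.reference.sequence)):
            raise ValueError("cut_site outside the reference")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if not (0 < self.frameshift_threshold < 1):
            raise ValueError("frameshift_threshold must be in (0, 1)")


class SpacerSite(NamedTuple):
    position: int  # 0-based start of the spacer on the forward strand
    strand: str  # '+' or '-'
    spacer: str  # spacer sequence 5'->3' on its own strand


class PairwiseAlignment(NamedTuple):
    ref_aln: str
    read_aln: str
    score: float


@dataclass
class IndelCall:
    read_id: str
    net_indel_length: int
    classification: str  # unedited | in_frame | frameshift
    callable: bool = True


@dataclass
class CloneSummary:
    clone_id: str
    n_reads: int
    n_unedited: int
    n_in_frame: int
    n_frameshift: int
    frameshift_fraction: float
    clone_class: str  # low | high


# ---------------------------------------------------------------------------
# Spacer-site scanning

_PAM_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T", "N": "ACGT",
    "R": "AG", "Y": "CT", "W": "AT", "S": "CG", "K": "GT", "M": "AC",
}


def _pam_matches(segment: str, pam: str) -> bool:
    return len(segment) == len(pam) and all(
        base in _PAM_CODES[code] for base, code in zip(segment, pam)
    )


def find_spacer_sites(
    seq: SequenceRecord | str, spacer_length: int = 19, pam: str = "NGG"
) -> list[SpacerSite]:
    """All positions on both strands where a spacer-length window is
    immediately followed by a PAM. The default 19-nt spacer matches an
    SpCas9 guide with a trimmed 5' base; positions are 0-based on the
    forward strand (for '-' hits, the forward-strand start of the window
    whose reverse complement is the spacer)."""
    if not (17 <= spacer_length <= 23):
        raise ValueError("spacer_length must be in [17, 23]")
    forward = (seq.sequence if isinstance(seq, SequenceRecord) else seq).upper()
    L = len(forward)
    site_len = spacer_length + len(pam)
    hits: list[SpacerSite] = []
    if L < site_len:
        return hits
    for i in range(L - site_len + 1):
        if _pam_matches(forward[i + spacer_length : i + site_len], pam):
            hits.append(SpacerSite(i, "+", forward[i : i + spacer_length]))
    rc = reverse_complement(forward)
    for i in range(L - site_len + 1):
        if _pam_matches(rc[i + spacer_length : i + site_len], pam):
            hits.append(SpacerSite(L - i - spacer_length, "-", rc[i : i + spacer_length]))
    return sorted(hits)


# ---------------------------------------------------------------------------
# Global alignment (Gotoh affine-gap Needleman-Wunsch)

MATCH = 1.0
MISMATCH = -1.0
GAP_OPEN = -4.0
GAP_EXTEND = -1.0

_NEG_INF = -1e30


def align_read(
    read: SequenceRecord | str,
    reference: SequenceRecord | str,
    match: float = MATCH,
    mismatch: float = MISMATCH,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> PairwiseAlignment:
    """Global alignment of a read against the reference with affine gaps.

    A gap of length L scores gap_open + L * gap_extend. Ties in the
    traceback are broken deterministically: match/mismatch over deletion
    (gap in the read) over insertion (gap in the reference).
    """
    ref = (reference.sequence if isinstance(reference, SequenceRecord) else reference).upper()
    qry = (read.sequence if isinstance(read, SequenceRecord) else read).upper()
    if not qry:
        raise ValueError("empty read")
    if not ref:
        raise ValueError("empty reference")
    if qry == ref:
        return PairwiseAlignment(ref, qry, match * len(ref))
    n, m = len(ref), len(qry)
    # M: ref[i] aligned to qry[j]; D: gap in read (ref consumed); I: gap in ref
    M = np.full((n + 1, m + 1), _NEG_INF)
    D = np.full((n + 1, m + 1), _NEG_INF)
    I = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        D[i, 0] = gap_open + i * gap_extend
    for j in range(1, m + 1):
        I[0, j] = gap_open + j * gap_extend
    for i in range(1, n + 1):
        ri = ref[i - 1]
        for j in range(1, m + 1):
            s = match if ri == qry[j - 1] else mismatch
            M[i, j] = max(M[i - 1, j - 1], D[i - 1, j - 1], I[i - 1, j - 1]) + s
            D[i, j] = max(
                M[i - 1, j] + gap_open + gap_extend,
                D[i - 1, j] + gap_extend,
                I[i - 1, j] + gap_open + gap_extend,
            )
            I[i, j] = max(
                M[i, j - 1] + gap_open + gap_extend,
                I[i, j - 1] + gap_extend,
                D[i, j - 1] + gap_open + gap_extend,
            )
    # traceback with fixed state preference M > D > I
    i, j = n, m
    state = max(("M", "D", "I"), key=lambda st: {"M": M, "D": D, "I": I}[st][n, m])
    # prefer M on ties, then D, then I
    for st in ("M", "D", "I"):
        if {"M": M, "D": D, "I": I}[st][n, m] == max(M[n, m], D[n, m], I[n, m]):
            state = st
            break
    score = {"M": M, "D": D, "I": I}[state][n, m]
    ref_aln: list[str] = []
    read_aln: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            s = match if ref[i - 1] == qry[j - 1] else mismatch
            ref_aln.append(ref[i - 1])
            read_aln.append(qry[j - 1])
            prev_score = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("D", D), ("I", I)):
                if mat[i, j] == prev_score:
                    state = st
                    break
        elif state == "D":
            ref_aln.append(ref[i - 1])
            read_aln.append("-")
            here = D[i, j]
            i -= 1
            if M[i, j] + gap_open + gap_extend == here:
                state = "M"
            elif D[i, j] + gap_extend == here:
                state = "D"
            else:
                state = "I"
        else:  # I
            ref_aln.append("-")
            read_aln.append(qry[j - 1])
            here = I[i, j]
            j -= 1
            if M[i, j] + gap_open + gap_extend == here:
                state = "M"
            elif I[i, j] + gap_extend == here:
                state = "I"
            else:
                state = "D"
        if i == 0 and j > 0:
            state = "I"
        elif j == 0 and i > 0:
            state = "D"
    return PairwiseAlignment("".join(reversed(ref_aln)), "".join(reversed(read_aln)), float(score))


# ---------------------------------------------------------------------------
# Indel calling

def call_indel(
    alignment: PairwiseAlignment, cfg: AmpliconConfig, read_id: str = "read"
) -> IndelCall:
    """Net indel length (insertions minus deletions) within cut_site +/-
    window, classified by reading-frame consequence. Frameshift iff the net
    length is nonzero and not a multiple of 3."""
    lo = cfg.cut_site - cfg.window
    hi = cfg.cut_site + cfg.window
    ref_len = len(cfg.reference.sequence)
    if hi < 0 or lo >= ref_len:
        return IndelCall(read_id, 0, "unedited", callable=False)
    inserted = deleted = 0
    ref_pos = 0  # 0-based coordinate of the next reference base
    for ref_char, read_char in zip(alignment.ref_aln, alignment.read_aln):
        if ref_char == "-":
            if lo <= ref_pos <= hi:
                inserted += 1
        else:
            if read_char == "-" and lo <= ref_pos <= hi:
                deleted += 1
            ref_pos += 1
    net = inserted - deleted
    # frame consequence depends only on the net length: cancelling indels
    # leave the frame intact and are treated as no edit
    if net == 0:
        classification = "unedited"
    elif net % 3 == 0:
        classification = "in_frame"
    else:
        classification = "frameshift"
    return IndelCall(read_id, net, classification)


def summarize_clone(
    reads: Iterable[SequenceRecord], cfg: AmpliconConfig, clone_id: str = "clone"
) -> CloneSummary:
    """Align and call every read; classify the clone by frameshift fraction.

    Alignments are cached per distinct read sequence (amplicon libraries are
    highly redundant), so cost scales with the number of unique haplotypes.
    """
    counts = {"unedited": 0, "in_frame": 0, "frameshift": 0}
    n_callable = 0
    cache: dict[str, PairwiseAlignment] = {}
    for read in reads:
        seq = read.sequence.upper()
        aln = cache.get(seq)
        if aln is None:
            aln = cache[seq] = align_read(seq, cfg.reference)
        call = call_indel(aln, cfg, read_id=read.id)
        if not call.callable:
            continue
        n_callable += 1
        counts[call.classification] += 1
    if n_callable == 0:
        raise ValueError(f"clone {clone_id}: no callable reads")
    fraction = counts["frameshift"] / n_callable
    return CloneSummary(
        clone_id=clone_id,
        n_reads=n_callable,
        n_unedited=counts["unedited"],
        n_in_frame=counts["in_frame"],
        n_frameshift=counts["frameshift"],
        frameshift_fraction=fraction,
        clone_class="high" if fraction >= cfg.frameshift_threshold else "low",
    )
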