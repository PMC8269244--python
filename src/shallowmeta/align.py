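"""Alignment backend contract.

The profiler consumes local-alignment hits in the ubiquitous BLAST
``outfmt 6`` tabular dialect, so any aligner (MegaBLAST, minimap2 with a
converter, ...) can act as the backend.  Two built-in backends are
provided:

* :func:`local_align` — an exact Smith–Waterman aligner for small
  instances; it serves as a deterministic oracle in tests and for
  spot-checking backend output.
* :class:`SeedExtendAligner` — a k-mer seed-and-extend nucleotide mapper
  (exact-seed lookup on a sorted 2-bit k-mer index, banded edit-distance
  verification via edlib).  It handles whole shallow data sets against
  multi-megabase reference sets on a single core.

E-values attached by the built-in backends are a monotone transform of the
alignment score, calibrated only so that thresholding behaves sensibly;
backend-supplied E-values are consumed verbatim.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

__all__ = [
    "AlignmentHit",
    "AlignmentError",
    "parse_tabular_hits",
    "write_tabular_hits",
    "local_align",
    "filter_hits",
    "SeedExtendAligner",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class AlignmentError(ValueError):
    """Malformed tabular hits or invalid alignment arguments."""


@dataclass(frozen=True)
class AlignmentHit:
    """One local-alignment record, backend-agnostic.

    Subject identifiers of the form ``accession|contig`` are split into
    ``subject_accession`` and ``subject_contig``; a bare identifier is used
    for both.  Coordinates are 1-based inclusive; a minus-strand hit keeps
    ``q_start <= q_end`` and carries ``strand='-'``.
    """

    query_id: str
    subject_accession: str
    subject_contig: str
    percent_identity: float
    align_length: int
    evalue: float
    bit_score: float
    query_cov: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise AlignmentError(
                f"hit {self.query_id!r}: q_start {self.q_start} > q_end {self.q_end}"
            )
        if not 0.0 <= self.percent_identity <= 100.0:
            raise AlignmentError(
                f"hit {self.query_id!r}: identity {self.percent_identity} outside [0,100]"
            )


def _split_subject(subject_id: str) -> tuple[str, str]:
    if "|" in subject_id:
        accession, contig = subject_id.split("|", 1)
        return accession, contig
    return subject_id, subject_id


def parse_tabular_hits(
    stream,
    query_lengths: Mapping[str, int] | None = None,
) -> list[AlignmentHit]:
    """Parse BLAST outfmt-6 rows (12 columns, optional 13th ``qcovs``).

    When ``qcovs`` is absent, query coverage is derived as
    ``100 * align_length / query_length``, which requires ``query_lengths``;
    rows for queries of unknown length get coverage 100 with alignment
    length as the only evidence.
    """
    hits: list[AlignmentHit] = []
    if isinstance(stream, (str, bytes)) or hasattr(stream, "__fspath__"):
        with open(stream) as fh:
            return parse_tabular_hits(fh, query_lengths)
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) not in (12, 13):
            raise AlignmentError(
                f"line {lineno}: expected 12 or 13 tab-separated columns, got {len(fields)}"
            )
        try:
            (qid, sid, pident, length, _mismatch, _gapopen,
             qstart, qend, sstart, send, evalue, bits) = fields[:12]
            pident_f = float(pident)
            length_i = int(length)
            qstart_i, qend_i = int(qstart), int(qend)
            sstart_i, send_i = int(sstart), int(send)
            evalue_f = float(evalue)
            bits_f = float(bits)
            qcov = float(fields[12]) if len(fields) == 13 else None
        except ValueError as exc:
            raise AlignmentError(f"line {lineno}: non-numeric field ({exc})") from None
        strand = "+"
        if sstart_i > send_i:
            strand = "-"
            sstart_i, send_i = send_i, sstart_i
        if qstart_i > qend_i:
            strand = "-" if strand == "+" else "+"
            qstart_i, qend_i = qend_i, qstart_i
        if qcov is None:
            if query_lengths is not None and qid in query_lengths:
                qcov = 100.0 * length_i / query_lengths[qid]
            else:
                qcov = 100.0
        accession, contig = _split_subject(sid)
        hits.append(
            AlignmentHit(
                query_id=qid,
                subject_accession=accession,
                subject_contig=contig,
                percent_identity=pident_f,
                align_length=length_i,
                evalue=evalue_f,
                bit_score=bits_f,
                query_cov=min(qcov, 100.0),
                q_start=qstart_i,
                q_end=qend_i,
                s_start=sstart_i,
                s_end=send_i,
                strand=strand,
            )
        )
    return hits


def write_tabular_hits(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as 13-column outfmt-6 rows (qcovs appended)."""
    with open(path, "w") as fh:
        for h in hits:
            sid = (
                h.subject_accession
                if h.subject_accession == h.subject_contig
                else f"{h.subject_accession}|{h.subject_contig}"
            )
            sstart, send = (h.s_start, h.s_end) if h.strand == "+" else (h.s_end, h.s_start)
            mismatches = round(h.align_length * (1 - h.percent_identity / 100.0))
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, sid, f"{h.percent_identity:.3f}", h.align_length,
                        mismatches, 0, h.q_start, h.q_end, sstart, send,
                        f"{h.evalue:.3g}", f"{h.bit_score:.1f}", f"{h.query_cov:.2f}",
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Smith–Waterman oracle


def synthetic_evalue(score: float, query_len: int, subject_len: int) -> float:
    """Monotone score→E-value transform for the built-in backends.

    ``E = m * n * 2**(-score)``: the classic search-space product with the
    raw score standing in for a calibrated bit score.  Adequate for
    thresholding; not comparable across scoring schemes.
    """
    log2_e = math.log2(max(query_len, 1)) + math.log2(max(subject_len, 1)) - score
    if log2_e < -996:
        return 1e-300
    return min(2.0**log2_e, 1e300)


def _sw_matrix(q: str, s: str, match: int, mismatch: int, gap: int) -> np.ndarray:
    n, m = len(q), len(s)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    qa = np.frombuffer(q.encode(), dtype=np.uint8)
    sa = np.frombuffer(s.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(sa == qa[i - 1], match, mismatch)
        prev = H[i - 1]
        row = H[i]
        diag = prev[:-1] + sub
        up = prev[1:] + gap
        best = np.maximum(diag, up)
        # left-gap dependency is sequential within the row
        running = 0
        for j in range(1, m + 1):
            v = best[j - 1]
            if running + gap > v:
                v = running + gap
            if v < 0:
                v = 0
            row[j] = v
            running = v
    return H


def _traceback(H, q, s, match, mismatch, gap, end_i, end_j):
    i, j = end_i, end_j
    matches = 0
    length = 0
    while i > 0 and j > 0 and H[i, j] > 0:
        here = H[i, j]
        sub = match if q[i - 1] == s[j - 1] else mismatch
        if here == H[i - 1, j - 1] + sub:
            matches += int(q[i - 1] == s[j - 1])
            length += 1
            i, j = i - 1, j - 1
        elif here == H[i - 1, j] + gap:
            length += 1
            i -= 1
        else:
            length += 1
            j -= 1
    return i + 1, j + 1, matches, length


def _best_local(q: str, s: str, match: int, mismatch: int, gap: int):
    H = _sw_matrix(q, s, match, mismatch, gap)
    score = int(H.max())
    if score <= 0:
        return None
    ends = np.argwhere(H == score)
    best = None
    for end_i, end_j in ends:
        qs, ss, matches, length = _traceback(
            H, q, s, match, mismatch, gap, int(end_i), int(end_j)
        )
        key = (qs, ss)
        if best is None or key < best[0]:
            best = (key, int(end_i), int(end_j), matches, length)
    (qs, ss), end_i, end_j, matches, length = best
    return score, qs, end_i, ss, end_j, matches, length


def local_align(
    query: str,
    subject: str,
    match: int = 1,
    mismatch: int = -1,
    gap: int = -2,
    query_id: str = "query",
    subject_id: str = "subject",
    search_reverse: bool = True,
) -> AlignmentHit | None:
    """Optimal Smith–Waterman local alignment of two nucleotide sequences.

    Both strands are searched (the reverse complement of the query against
    the subject); ties prefer the forward strand, then the alignment with
    the smallest ``q_start`` and ``s_start``.  Intended for small instances
    (reads, contig segments, subjects up to ~100 kb); use
    :class:`SeedExtendAligner` for bulk work.
    """
    if not query or not subject:
        raise AlignmentError("local_align requires non-empty sequences")
    query = query.upper()
    subject = subject.upper()
    candidates = []
    fwd = _best_local(query, subject, match, mismatch, gap)
    if fwd is not None:
        candidates.append(("+", query, fwd))
    if search_reverse:
        rc = reverse_complement(query)
        rev = _best_local(rc, subject, match, mismatch, gap)
        if rev is not None:
            candidates.append(("-", rc, rev))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-c[2][0], c[0]))  # score desc, '+' first
    strand, oriented_query, (score, qs, qe, ss, se, matches, length) = candidates[0]
    if strand == "-":
        # map coordinates back onto the original (plus-strand) query
        n = len(query)
        qs, qe = n - qe + 1, n - qs + 1
    identity = 100.0 * matches / length if length else 0.0
    accession, contig = _split_subject(subject_id)
    return AlignmentHit(
        query_id=query_id,
        subject_accession=accession,
        subject_contig=contig,
        percent_identity=identity,
        align_length=length,
        evalue=synthetic_evalue(score, len(query), len(subject)),
        bit_score=float(score),
        query_cov=100.0 * (qe - qs + 1) / len(query),
        q_start=qs,
        q_end=qe,
        s_start=ss,
        s_end=se,
        strand=strand,
    )


# ---------------------------------------------------------------------------
# Hit filtering


def filter_hits(
    hits: Sequence[AlignmentHit],
    evalue_max: float = 1e-5,
    min_query_cov: float = 95.0,
    max_hits: int = 100,
) -> list[AlignmentHit]:
    """Apply the per-read hit gates and keep the strongest hits.

    Hits failing the E-value or query-coverage gate are removed; survivors
    are sorted by bit score (ties: higher identity, then subject accession)
    and truncated to ``max_hits`` — the classifier works from this bounded
    best-hit list rather than a single best hit.
    """
    survivors = [
        h for h in hits if h.evalue <= evalue_max and h.query_cov >= min_query_cov
    ]
    survivors.sort(
        key=lambda h: (-h.bit_score, -h.percent_identity, h.subject_accession, h.subject_contig)
    )
    return survivors[:max_hits]


# ---------------------------------------------------------------------------
# Seed-and-extend bulk mapper

_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i


def _encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """2-bit codes of all k-mers plus a validity mask (no N in window)."""
    n = arr.shape[0]
    if n < k:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    codes = np.zeros(n - k + 1, dtype=np.uint64)
    for j in range(k):
        codes |= arr[j : n - k + 1 + j].astype(np.uint64) << np.uint64(2 * (k - 1 - j))
    bad = np.cumsum(np.concatenate(([0], (arr == 4).astype(np.int64))))
    valid = (bad[k:] - bad[:-k]) == 0
    return codes, valid


class SeedExtendAligner:
    """Exact-k-mer-seeded nucleotide read mapper over a reference set.

    References (``(accession, contig_id, sequence)`` triples) are
    concatenated with ``N`` spacers and indexed as a sorted array of 2-bit
    k-mer codes.  A query is mapped by looking up seeds sampled along both
    strands, clustering seed votes by alignment start (within an indel
    band), and verifying each candidate locus with an infix edit-distance
    alignment (edlib).  Identity is computed from the edit distance over
    the alignment span, so substitutions and indels both count.

    Parameters
    ----------
    k : seed length (default 21); seeds are sampled every ``seed_stride``
        bases (default 12) so several independent seeds cover a 150-bp read.
    max_candidates : number of distinct loci verified per strand.
    """

    def __init__(
        self,
        references: Iterable[tuple[str, str, str]],
        k: int = 21,
        seed_stride: int = 12,
        max_candidates: int = 8,
        band_fraction: float = 0.12,
    ):
        self.k = k
        self.seed_stride = seed_stride
        self.max_candidates = max_candidates
        self.band_fraction = band_fraction
        parts: list[np.ndarray] = []
        bounds: list[int] = [0]
        names: list[tuple[str, str]] = []
        spacer = np.full(k, 4, dtype=np.uint8)
        offset = 0
        seqs: list[str] = []
        for accession, contig_id, seq in references:
            arr = _encode(seq)
            parts.append(arr)
            parts.append(spacer)
            offset += arr.shape[0] + k
            bounds.append(offset)
            names.append((accession, contig_id))
            seqs.append(seq.upper())
        if not names:
            raise AlignmentError("SeedExtendAligner requires at least one reference")
        self._concat = np.concatenate(parts)
        self._bounds = np.asarray(bounds, dtype=np.int64)
        self._names = names
        self._seqs = seqs
        self.total_bases = int(sum(len(s) for s in seqs))
        codes, valid = _kmer_codes(self._concat, k)
        positions = np.nonzero(valid)[0].astype(np.int64)
        codes = codes[positions]
        order = np.argsort(codes, kind="stable")
        self._sorted_codes = codes[order]
        self._sorted_positions = positions[order]

    # -- seed lookup -----------------------------------------------------

    def _candidate_starts(self, arr: np.ndarray) -> np.ndarray:
        codes, valid = _kmer_codes(arr, self.k)
        if codes.size == 0:
            return np.empty(0, dtype=np.int64)
        offsets = np.arange(codes.shape[0], dtype=np.int64)
        take = np.zeros(codes.shape[0], dtype=bool)
        take[:: self.seed_stride] = True
        take[-1] = True
        sel = valid & take
        codes, offsets = codes[sel], offsets[sel]
        if codes.size == 0:
            return np.empty(0, dtype=np.int64)
        lo = np.searchsorted(self._sorted_codes, codes, side="left")
        hi = np.searchsorted(self._sorted_codes, codes, side="right")
        starts: list[np.ndarray] = []
        for l, h, off in zip(lo, hi, offsets):
            if h > l:
                hits = self._sorted_positions[l : min(h, l + 64)]
                starts.append(hits - off)
        if not starts:
            return np.empty(0, dtype=np.int64)
        return np.concatenate(starts)

    def _cluster(self, starts: np.ndarray, band: int) -> list[tuple[int, int]]:
        """Group candidate starts within ``band`` bases; return (start, votes)."""
        if starts.size == 0:
            return []
        starts = np.sort(starts)
        groups: list[tuple[int, int]] = []
        anchor = starts[0]
        count = 1
        for s in starts[1:]:
            if s - anchor <= band:
                count += 1
            else:
                groups.append((int(anchor), count))
                anchor, count = s, 1
        groups.append((int(anchor), count))
        groups.sort(key=lambda g: (-g[1], g[0]))
        return groups[: self.max_candidates]

    def _locate(self, pos: int) -> int | None:
        idx = int(np.searchsorted(self._bounds, pos, side="right")) - 1
        if idx < 0 or idx >= len(self._names):
            return None
        return idx

    def _verify(self, query: str, strand: str, start: int, query_id: str) -> AlignmentHit | None:
        idx = self._locate(max(start, 0))
        if idx is None:
            return None
        ref_seq = self._seqs[idx]
        ref_off = int(self._bounds[idx])
        local = start - ref_off
        qlen = len(query)
        band = max(8, int(self.band_fraction * qlen))
        w_start = max(0, local - band)
        w_end = min(len(ref_seq), local + qlen + band)
        window = ref_seq[w_start:w_end]
        if len(window) < self.k:
            return None
        res = edlib.align(query, window, mode="HW", task="locations")
        dist = res["editDistance"]
        if dist < 0 or not res["locations"]:
            return None
        loc = res["locations"][0]
        span = loc[1] - loc[0] + 1
        aln_len = max(qlen, span)
        matches = aln_len - dist
        identity = 100.0 * matches / aln_len
        score = matches - dist  # +1 match / -1 edit, gap-open folded in
        accession, contig = self._names[idx]
        return AlignmentHit(
            query_id=query_id,
            subject_accession=accession,
            subject_contig=contig,
            percent_identity=identity,
            align_length=aln_len,
            evalue=synthetic_evalue(float(score), qlen, self.total_bases),
            bit_score=float(score),
            query_cov=100.0,
            q_start=1,
            q_end=qlen,
            s_start=w_start + loc[0] + 1,
            s_end=w_start + loc[1] + 1,
            strand=strand,
        )

    def map_read(self, query: str, query_id: str = "query") -> list[AlignmentHit]:
        """Best hits of one read against the reference set, both strands."""
        if not query:
            raise AlignmentError("cannot map an empty read")
        query = query.upper()
        band = max(8, int(self.band_fraction * len(query)))
        hits: dict[tuple[str, str, str], AlignmentHit] = {}
        for strand, oriented in (("+", query), ("-", reverse_complement(query))):
            arr = _encode(oriented)
            for start, _votes in self._cluster(self._candidate_starts(arr), band):
                hit = self._verify(oriented, strand, start, query_id)
                if hit is None:
                    continue
                key = (hit.subject_accession, hit.subject_contig, strand)
                kept = hits.get(key)
                if kept is None or hit.bit_score > kept.bit_score:
                    hits[key] = hit
        out = list(hits.values())
        out.sort(key=lambda h: (-h.bit_score, h.subject_accession, h.subject_contig))
        return out

    def map_long_query(self, query: str, query_id: str = "query") -> list[AlignmentHit]:
        """Map a long query (contig) by its best-supported locus per subject.

        Same machinery as :meth:`map_read`; query coverage is reported from
        the verified alignment span rather than assumed full-length.
        """
        hits = self.map_read(query, query_id)
        qlen = len(query)
        adjusted = []
        for h in hits:
            span = min(h.align_length, qlen)
            adjusted.append(replace(h, query_cov=100.0 * span / qlen))
        return adjusted
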