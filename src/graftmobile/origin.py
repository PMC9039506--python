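"""Species-of-origin read assignment and mobile-transcript calling.

The two species' transcriptomes are organized as homolog pairs of equal
length (substitution-only divergence, no indels), so position *i* on one
homolog corresponds to position *i* on the other.  The positions where the
two homologs carry different bases are *diagnostic sites*: a sequencing
read overlapping such a site reveals which species it was transcribed in.

A transcript is called *mobile* into a heterograft tissue when enough reads
of the foreign species are recovered there, reproducibly across replicates,
while the matched homograft — where no graft junction exists to cross —
shows no such reads (the background veto against mapping artifacts).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .design import GraftSample

# read-origin categories
ORIGIN_A = "origin_a"
ORIGIN_B = "origin_b"
AMBIGUOUS = "ambiguous"
UNINFORMATIVE = "uninformative"
UNMAPPED = "unmapped"


@dataclass(frozen=True)
class HomologPair:
    """A pair of homologous transcripts, one per species, aligned position-wise."""

    id_a: str
    id_b: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError(
                f"homolog pair {self.id_a}/{self.id_b} has unequal lengths; "
                "align upstream before origin assignment"
            )
        if self.id_a == self.id_b:
            raise ValueError("pair ids must be distinct")

    @property
    def length(self) -> int:
        return len(self.seq_a)

    @property
    def species_a(self) -> str:
        return self.id_a.split("_")[0]

    @property
    def species_b(self) -> str:
        return self.id_b.split("_")[0]


@dataclass(frozen=True)
class DiagnosticSite:
    """A position where the two homologs disagree; 0-based."""

    position: int
    allele_a: str
    allele_b: str

    def __post_init__(self) -> None:
        if self.allele_a == self.allele_b:
            raise ValueError("diagnostic site alleles must differ")


def find_diagnostic_sites(pair: HomologPair) -> list[DiagnosticSite]:
    """All positions where the homologs differ and neither base is N, ascending."""
    a = np.frombuffer(pair.seq_a.encode(), dtype="S1")
    b = np.frombuffer(pair.seq_b.encode(), dtype="S1")
    differing = np.flatnonzero((a != b) & (a != b"N") & (b != b"N"))
    return [
        DiagnosticSite(int(p), pair.seq_a[p], pair.seq_b[p]) for p in differing
    ]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def _classify_at(
    read: np.ndarray,
    pair: HomologPair,
    sites: list[DiagnosticSite],
    offset: int,
) -> str:
    """Origin category for a read placed at ``offset`` on the pair."""
    end = offset + len(read)
    covered = [s for s in sites if offset <= s.position < end]
    if not covered:
        return UNINFORMATIVE
    all_a = all(chr(read[s.position - offset]) == s.allele_a for s in covered)
    all_b = all(chr(read[s.position - offset]) == s.allele_b for s in covered)
    if all_a and not all_b:
        return ORIGIN_A
    if all_b and not all_a:
        return ORIGIN_B
    return AMBIGUOUS


def assign_read_origin(
    read: str,
    pair: HomologPair,
    sites: list[DiagnosticSite] | None = None,
    max_mismatch: int = 1,
) -> tuple[str, int | None]:
    """Place one read on a homolog pair and classify its species of origin.

    The read is located by an exhaustive sliding-window scan against both
    homologs; the placement minimizing the mismatch count is kept and must
    reach ``max_mismatch`` or fewer mismatches against at least one homolog,
    otherwise the read is ``unmapped``.  The origin is the species whose
    alleles the read carries at *all* covered diagnostic sites; sites
    supporting both species -> ``ambiguous``; no covered site ->
    ``uninformative``.

    Returns ``(category, offset)`` with a 0-based offset (None if unmapped).
    """
    if len(read) > pair.length:
        raise ValueError("read longer than transcript")
    if sites is None:
        sites = find_diagnostic_sites(pair)
    r = _encode(read)
    best_mm, best_off = None, None
    for seq in (pair.seq_a, pair.seq_b):
        arr = _encode(seq)
        windows = np.lib.stride_tricks.sliding_window_view(arr, len(r))
        mismatches = np.count_nonzero(windows != r, axis=1)
        off = int(np.argmin(mismatches))
        mm = int(mismatches[off])
        if best_mm is None or mm < best_mm:
            best_mm, best_off = mm, off
    if best_mm is None or best_mm > max_mismatch:
        return UNMAPPED, None
    return _classify_at(r, pair, sites, best_off), best_off


class ReadOriginIndex:
    """Seed-and-verify placement of many reads against many homolog pairs.

    Exact k-mer seeds taken along the read locate candidate (pair, offset)
    placements; each candidate is verified by counting mismatches against
    both homologs at that offset.  With ``max_mismatch`` = 1 and several
    seeds per read, a read with at most one substitution (divergence or
    sequencing error) always retains an exact seed, so the seed stage loses
    essentially nothing relative to the exhaustive scan.
    """

    def __init__(self, pairs: Iterable[HomologPair], k: int = 25, max_mismatch: int = 1):
        self.pairs = list(pairs)
        self.k = k
        self.max_mismatch = max_mismatch
        self.sites = [find_diagnostic_sites(p) for p in self.pairs]
        self._arr_a = [_encode(p.seq_a) for p in self.pairs]
        self._arr_b = [_encode(p.seq_b) for p in self.pairs]
        self._index: dict[bytes, list[tuple[int, int]]] = {}
        for pi, p in enumerate(self.pairs):
            for seq in (p.seq_a, p.seq_b):
                enc = seq.encode()
                for pos in range(0, len(enc) - k + 1):
                    self._index.setdefault(enc[pos : pos + k], []).append((pi, pos))

    def _seed_candidates(self, read: bytes) -> set[tuple[int, int]]:
        k = self.k
        offsets = list(range(0, len(read) - k + 1, k))[:4]
        if offsets and offsets[-1] != len(read) - k:
            offsets.append(len(read) - k)
        cands: set[tuple[int, int]] = set()
        for so in offsets:
            for pi, pos in self._index.get(read[so : so + k], ()):
                off = pos - so
                if 0 <= off <= self.pairs[pi].length - len(read):
                    cands.add((pi, off))
        return cands

    def assign(self, read: str) -> tuple[str, int | None, int | None]:
        """Classify one read; returns (category, pair index, offset)."""
        r = _encode(read)
        best = None  # (mismatches, pair index, offset)
        for pi, off in self._seed_candidates(read.encode()):
            mm_a = int(np.count_nonzero(self._arr_a[pi][off : off + len(r)] != r))
            mm_b = int(np.count_nonzero(self._arr_b[pi][off : off + len(r)] != r))
            mm = min(mm_a, mm_b)
            if best is None or mm < best[0] or (mm == best[0] and (pi, off) < best[1:]):
                best = (mm, pi, off)
        if best is None or best[0] > self.max_mismatch:
            return UNMAPPED, None, None
        _, pi, off = best
        return _classify_at(r, self.pairs[pi], self.sites[pi], off), pi, off

    def count_origins(self, reads: Iterable[tuple[str, str]]) -> dict[str, dict[int, int]]:
        """Per-species origin-assigned read counts per pair for one sample.

        Returns ``{species: {pair index: count}}``; ambiguous, uninformative
        and unmapped reads are excluded (never fractionally split).
        """
        counts: dict[str, dict[int, int]] = {}
        for _, seq in reads:
            category, pi, _ = self.assign(seq)
            if category == ORIGIN_A:
                species = self.pairs[pi].species_a
            elif category == ORIGIN_B:
                species = self.pairs[pi].species_b
            else:
                continue
            counts.setdefault(species, {})[pi] = counts.setdefault(species, {}).get(pi, 0) + 1
        return counts


def pairs_from_map(
    references: dict[str, dict[str, str]], pair_map: pd.DataFrame
) -> list[HomologPair]:
    """Build HomologPair objects from two reference sets and the id map."""
    by_id = {tid: seq for sp in references.values() for tid, seq in sp.items()}
    return [
        HomologPair(row.id_a, row.id_b, by_id[row.id_a], by_id[row.id_b])
        for row in pair_map.itertuples(index=False)
    ]


def call_mobile_transcripts(
    reads_by_sample: dict[str, list[tuple[str, str]]],
    pairs: list[HomologPair],
    min_reads: int = 5,
    min_replicates: int = 2,
    max_background: int = 0,
    k: int = 25,
    max_mismatch: int = 1,
) -> pd.DataFrame:
    """Call graft-mobile transcripts across the whole design.

    For every heterograft sample group (graft x tissue x condition) the
    foreign species' origin-assigned reads are counted per transcript and
    replicate.  A transcript is mobile into that destination iff

    1. foreign reads summed over replicates >= ``min_reads``,
    2. it is detected in >= ``min_replicates`` replicates, and
    3. the matched homograft of the resident tissue (same tissue and
       condition) shows <= ``max_background`` foreign-looking reads —
       reads that appear foreign where no junction exists are artifacts.

    Returns one row per (transcript, destination graft, tissue, condition)
    with per-replicate counts, the background count and the boolean call.
    """
    index = ReadOriginIndex(pairs, k=k, max_mismatch=max_mismatch)
    samples = {key: GraftSample.from_key(key) for key in reads_by_sample}
    counts = {
        key: index.count_origins(reads) for key, reads in reads_by_sample.items()
    }

    het_groups: dict[tuple[str, str, str], list[str]] = {}
    for key, s in samples.items():
        if s.is_heterograft:
            het_groups.setdefault((s.graft, s.tissue, s.condition), []).append(key)

    rows = []
    for (graft, tissue, condition), keys in sorted(het_groups.items()):
        keys.sort(key=lambda k_: samples[k_].replicate)
        foreign = samples[keys[0]].foreign_species
        background_keys = [samples[k_].matched_homograft().key for k_ in keys]
        missing = [bk for bk in background_keys if bk not in reads_by_sample]
        if missing:
            raise ValueError(
                f"missing matched homograft background sample(s): {sorted(set(missing))}"
            )
        for pi, pair in enumerate(pairs):
            tid = pair.id_a if pair.species_a == foreign else pair.id_b
            rep_counts = [counts[k_].get(foreign, {}).get(pi, 0) for k_ in keys]
            background = sum(
                counts[bk].get(foreign, {}).get(pi, 0) for bk in set(background_keys)
            )
            total = sum(rep_counts)
            detected = sum(1 for c in rep_counts if c > 0)
            is_mobile = (
                total >= min_reads
                and detected >= min_replicates
                and background <= max_background
            )
            if total == 0 and background == 0:
                continue
            rows.append(
                {
                    "transcript": tid,
                    "origin": foreign,
                    "graft": graft,
                    "tissue": tissue,
                    "condition": condition,
                    **{f"count_rep{i + 1}": c for i, c in enumerate(rep_counts)},
                    "total_reads": total,
                    "n_replicates_detected": detected,
                    "background": background,
                    "is_mobile": is_mobile,
                }
            )
    columns = [
        "transcript",
        "origin",
        "graft",
        "tissue",
        "condition",
        "total_reads",
        "n_replicates_detected",
        "background",
        "is_mobile",
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)
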