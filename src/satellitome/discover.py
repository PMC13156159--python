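"""Iterative satDNA discovery from short reads.

Tandem-repeat monomers leave a signature in k-mer space: the k-mers of a
homogeneous tandem array form a closed cycle in the k-mer adjacency graph
(successors overlap by k-1), with per-k-mer multiplicity far above the
background of a low-coverage read sample.  Discovery walks that graph:

1. subsample read pairs;
2. count k-mers of the reads and their reverse complements, keep those at
   or above a small absolute multiplicity floor;
3. start greedy heaviest-successor walks from high-multiplicity k-mers;
   a walk that returns into its own path closes a cycle, which is spelled
   into a circular consensus;
4. refine each consensus by one round of read realignment and per-column
   majority vote; keep candidates with enough supporting reads and k-mer
   mass;
5. subtract matching read pairs from the library and repeat until a round
   yields nothing new.

The walk-start threshold (not the admission floor) is what separates
repetitive signal from background: in a sub-1x coverage sample, background
k-mers have multiplicity near the sample coverage while array k-mers scale
with family abundance, so walks seeded at several times the background
multiplicity start on repeats only.  Cycle k-mers are marked consumed so
each family is reported once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import edlib
import numpy as np

from .align import reverse_complement, similarity
from .errors import InvalidInputError
from .simulate import ReadLibrary

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODE_BASE = "ACGT"


@dataclass(frozen=True)
class CandidateFamily:
    """A tandem-repeat consensus proposed by one discovery round."""

    consensus: str
    supporting_read_count: int
    discovery_round: int
    est_abundance: float

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def abundance(self) -> float:
        """Alias so candidates satisfy the catalog tiering interface."""
        return self.est_abundance


@dataclass
class DiscoveryParams:
    """Knobs of the iterative discovery loop (desk-scale defaults).

    ``subsample_pairs`` bounds per-round work the way the much larger
    fixed subsample of a production run does; ``full_scale()`` returns
    the full-scale profile.
    """

    subsample_pairs: int = 50_000
    k: int = 21
    min_kmer_count: int = 2        # admission floor for graph k-mers
    start_min_count: int = 8       # walk-start multiplicity threshold
    min_abundance: float = 2e-4    # candidate floor, k-mer-mass estimate
    min_support: int = 50          # supporting reads per candidate
    subtract_identity: float = 80.0
    subtract_coverage: float = 0.5
    max_rounds: int = 8
    max_walk_starts: int = 4000
    refine_reads: int = 200
    seed: int = 0

    @classmethod
    def full_scale(cls, **overrides) -> "DiscoveryParams":
        params = cls(subsample_pairs=500_000, **overrides)
        return params


@dataclass
class RoundLog:
    round: int
    candidates_found: int
    reads_remaining: int


def subsample_reads(lib: ReadLibrary, n_pairs: int, seed: int) -> ReadLibrary:
    """Uniform sample of read pairs without replacement, order-preserving."""
    if n_pairs > lib.n_pairs:
        raise InvalidInputError(
            f"requested {n_pairs} pairs from a library of {lib.n_pairs}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(lib.n_pairs, size=n_pairs, replace=False))
    pairs = [lib.read_pairs[i] for i in idx]
    manifest = []
    for i in idx:
        manifest.append(lib.source_manifest[2 * i])
        manifest.append(lib.source_manifest[2 * i + 1])
    return ReadLibrary(pairs, lib.read_length, manifest)


def _kmer_spectrum(reads: list[str], k: int
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Sorted unique k-mer codes (base-4 integers, both strands) + counts."""
    chunks = []
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    for strand_reads in (reads, [reverse_complement(r) for r in reads]):
        blob = ("N".join(strand_reads)).encode("ascii")
        codes = _BASE_CODE[np.frombuffer(blob, dtype=np.uint8)]
        if codes.size < k:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, k)
        valid = ~(windows == 255).any(axis=1)
        if valid.any():
            vals = windows[valid].astype(np.int64) @ powers
            chunks.append(vals)
    if not chunks:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64), 0
    allvals = np.concatenate(chunks)
    uniq, counts = np.unique(allvals, return_counts=True)
    return uniq, counts, int(allvals.size)


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_CODE_BASE[code & 3])
        code >>= 2
    return "".join(reversed(out))


def _canonical_rotation(seq: str) -> str:
    """Lexicographically minimal rotation over both strands."""
    best = None
    for s in (seq, reverse_complement(seq)):
        dbl = s + s
        for r in range(len(s)):
            rot = dbl[r:r + len(s)]
            if best is None or rot < best:
                best = rot
    return best


def _multimer_similarity(a: str, b: str) -> float:
    """Circular similarity that treats whole multimers as the same family.

    A greedy graph walk can close a cycle spanning several monomer copies
    (a k-copy variant ring); comparing the longer candidate against a
    tandem extension of the shorter recognises such multimers, which plain
    monomer-vs-monomer alignment would score near the gap floor.
    """
    short, long_ = sorted((a, b), key=len)
    if len(long_) >= 2 * len(short):
        short = short * round(len(long_) / len(short))
    return similarity(short, long_)


def _tandem_extend(consensus: str, read_length: int) -> str:
    reps = max(2, math.ceil((read_length + len(consensus))
                            / len(consensus)) + 1)
    return consensus * reps


def _read_matches(read: str, target: str, min_identity: float
                  ) -> tuple[int, str] | None:
    """Best infix edit alignment of the read (either strand) to the target.

    Returns (edit distance, strand) when the distance stays within the
    identity budget; None otherwise.
    """
    k_budget = int((1.0 - min_identity / 100.0) * len(read))
    best = None
    for strand, query in (("+", read), ("-", reverse_complement(read))):
        res = edlib.align(query, target, mode="HW", task="distance",
                          k=k_budget)
        d = res["editDistance"]
        if d != -1 and (best is None or d < best[0]):
            best = (d, strand)
    return best


def _refine_consensus(consensus: str, reads: list[str],
                      min_identity: float = 70.0,
                      max_reads: int = 200) -> tuple[str, int]:
    """One round of read realignment + per-column majority vote.

    Returns the refined consensus and the number of supporting reads in
    ``reads`` (all reads are tested for support; at most ``max_reads``
    vote, keeping the refinement cost bounded).
    """
    L = len(consensus)
    target = _tandem_extend(consensus, max(len(r) for r in reads))
    votes = np.zeros((L, 4), dtype=np.int64)
    support = 0
    voted = 0
    for read in reads:
        hit = _read_matches(read, target, min_identity)
        if hit is None:
            continue
        support += 1
        if voted >= max_reads:
            continue
        voted += 1
        query = read if hit[1] == "+" else reverse_complement(read)
        res = edlib.align(query, target, mode="HW", task="path")
        if res["editDistance"] == -1:
            continue
        t_pos = res["locations"][0][0]
        q_pos = 0
        for length, op in _parse_cigar(res["cigar"]):
            if op in ("=", "X", "M"):
                for off in range(length):
                    code = _BASE_CODE[ord(query[q_pos + off])]
                    if code != 255:
                        votes[(t_pos + off) % L, code] += 1
                t_pos += length
                q_pos += length
            elif op == "D":       # deletion in query: target advances
                t_pos += length
            elif op == "I":       # insertion in query
                q_pos += length
    refined = list(consensus)
    for i in range(L):
        if votes[i].sum() > 0:
            refined[i] = _CODE_BASE[int(votes[i].argmax())]
    return "".join(refined), support


def _parse_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def detect_tandem_families(reads: ReadLibrary, k: int = 21,
                           min_abundance: float = 2e-4,
                           min_kmer_count: int = 2,
                           start_min_count: int = 8,
                           min_support: int = 50,
                           max_walk_starts: int = 4000,
                           refine_reads: int = 200,
                           discovery_round: int = 1
                           ) -> list[CandidateFamily]:
    """Propose tandem-repeat consensus candidates from a read sample.

    Returns an empty list (not an error) when no k-mer clears the floors.
    Candidates are sorted by decreasing k-mer-mass abundance estimate and
    deduplicated at >95% circular similarity within the round.
    """
    if reads.n_pairs == 0:
        raise InvalidInputError("empty read library")
    if not (11 <= k < reads.read_length):
        raise InvalidInputError(
            f"k={k} outside [11, read_length={reads.read_length})")
    seqs = reads.reads()
    uniq, counts, total_mass = _kmer_spectrum(seqs, k)
    if total_mass == 0:
        return []
    kept = counts >= min_kmer_count
    uniq, counts = uniq[kept], counts[kept]
    if uniq.size == 0:
        return []

    def count_of(code: int) -> int:
        i = np.searchsorted(uniq, code)
        if i < uniq.size and uniq[i] == code:
            return int(counts[i])
        return 0

    start_order = np.argsort(counts, kind="stable")[::-1]
    start_order = start_order[counts[start_order] >= start_min_count]
    consumed: set[int] = set()
    dead_starts: set[int] = set()
    suffix_mod = 4 ** (k - 1)
    raw: list[tuple[str, float]] = []
    starts_used = 0
    max_walk_len = 8192
    for si in start_order[:max_walk_starts * 4]:
        node = int(uniq[si])
        if node in consumed or node in dead_starts:
            continue
        starts_used += 1
        if starts_used > max_walk_starts:
            break
        path: list[int] = []
        path_pos: dict[int, int] = {}
        cycle: list[int] | None = None
        while len(path) < max_walk_len:
            if node in path_pos:
                cycle = path[path_pos[node]:]
                break
            path_pos[node] = len(path)
            path.append(node)
            base_next = (node % suffix_mod) * 4
            best_c, best_succ = 0, -1
            for c in range(4):
                succ = base_next + c
                if succ in consumed:
                    continue
                cnt = count_of(succ)
                if cnt > best_c:
                    best_c, best_succ = cnt, succ
            if best_succ < 0:
                break
            node = best_succ
        if cycle is None or len(cycle) < 10:
            for n in path:
                dead_starts.add(n)
            continue
        monomer = "".join(_decode(n, k)[0] for n in cycle)
        cyc_mass = sum(count_of(n) for n in cycle)
        rc_nodes = []
        rc = reverse_complement(monomer)
        dbl = rc + rc
        for r in range(len(rc)):
            kmer = (dbl + dbl)[r:r + k] if len(rc) < k else dbl[r:r + k]
            code = 0
            ok = True
            for ch in kmer:
                v = _BASE_CODE[ord(ch)]
                if v == 255:
                    ok = False
                    break
                code = code * 4 + int(v)
            if ok:
                rc_nodes.append(code)
                cyc_mass += count_of(code)
        consumed.update(cycle)
        consumed.update(rc_nodes)
        est = cyc_mass / total_mass
        if est >= min_abundance:
            raw.append((monomer, est))

    candidates: list[CandidateFamily] = []
    # shorter units first so a multimer ring dedupes against its monomer
    for monomer, est in sorted(raw, key=lambda t: (len(t[0]), -t[1])):
        refined, support = _refine_consensus(
            _canonical_rotation(monomer), seqs, max_reads=refine_reads)
        refined = _canonical_rotation(refined)
        if support < min_support:
            continue
        if any(_multimer_similarity(refined, c.consensus) > 95.0
               for c in candidates):
            continue
        candidates.append(CandidateFamily(
            consensus=refined, supporting_read_count=support,
            discovery_round=discovery_round, est_abundance=est))
    return candidates


def subtract_matching_reads(lib: ReadLibrary, families: list,
                            identity_threshold: float = 80.0,
                            coverage_threshold: float = 0.5) -> ReadLibrary:
    """Remove read pairs matching any family consensus.

    A pair is removed when either mate aligns to a family's tandem-extended
    consensus at the identity threshold over at least the coverage fraction
    of the read (tested on the whole read and, for partial coverage, on its
    two flanks).  Both mates are removed together.
    """
    if not (0.0 < identity_threshold <= 100.0):
        raise InvalidInputError("identity_threshold must be in (0, 100]")
    if not (0.0 < coverage_threshold <= 1.0):
        raise InvalidInputError("coverage_threshold must be in (0, 1]")
    if not families:
        return lib
    targets = [
        _tandem_extend(f.consensus, lib.read_length) for f in families]

    def mate_hits(read: str) -> bool:
        windows = [read]
        if coverage_threshold < 1.0:
            w = max(30, int(len(read) * coverage_threshold))
            if w < len(read):
                windows.extend((read[:w], read[-w:]))
        for target in targets:
            for window in windows:
                if _read_matches(window, target, identity_threshold):
                    return True
        return False

    pairs = []
    manifest = []
    for i, (fwd, rev) in enumerate(lib.read_pairs):
        if mate_hits(fwd) or mate_hits(rev):
            continue
        pairs.append((fwd, rev))
        manifest.append(lib.source_manifest[2 * i])
        manifest.append(lib.source_manifest[2 * i + 1])
    return ReadLibrary(pairs, lib.read_length, manifest)


@dataclass
class DiscoveryResult:
    families: list[CandidateFamily]
    rounds: list[RoundLog] = field(default_factory=list)


def iterate_discovery(lib: ReadLibrary, params: DiscoveryParams | None = None
                      ) -> DiscoveryResult:
    """Subsample -> detect -> subtract until a round finds nothing new.

    Termination is guaranteed: the library only shrinks and the round count
    is capped.  Candidates carry the round in which they were first found;
    a candidate over 95% similar to an already-accepted one is not new.
    """
    params = params or DiscoveryParams()
    accepted: list[CandidateFamily] = []
    logs: list[RoundLog] = []
    remaining = lib
    for round_no in range(1, params.max_rounds + 1):
        if remaining.n_pairs == 0:
            break
        n = min(params.subsample_pairs, remaining.n_pairs)
        sample = subsample_reads(remaining, n, params.seed + round_no)
        found = detect_tandem_families(
            sample, k=params.k, min_abundance=params.min_abundance,
            min_kmer_count=params.min_kmer_count,
            start_min_count=params.start_min_count,
            min_support=params.min_support,
            max_walk_starts=params.max_walk_starts,
            refine_reads=params.refine_reads,
            discovery_round=round_no)
        new = [c for c in found
               if not any(_multimer_similarity(c.consensus, a.consensus)
                          > 95.0 for a in accepted)]
        logs.append(RoundLog(round_no, len(new), remaining.n_pairs))
        if not new:
            break
        accepted.extend(new)
        remaining = subtract_matching_reads(
            remaining, new, params.subtract_identity,
            params.subtract_coverage)
    return DiscoveryResult(accepted, logs)
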