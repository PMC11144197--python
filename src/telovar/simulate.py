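"""Synthetic telomere arrays, WGS-like reads, and C-tail terminal reads.

The generator gives every downstream stage a testable input with known
ground truth, built on the same two-allele re-association model the
estimator assumes:

* :func:`simulate_telomere_array` grows a telomere one hexamer at a time.
  After each addition the enzyme either continues processively
  (probability ``p_x`` of the current allele) or dissociates; a
  re-associating enzyme carries the variant template with probability
  ``rho``. A deposited hexamer is then overwritten, with probability
  ``degeneracy``, by a uniformly random hexamer that is neither TTAGGG nor
  TTAGGT — a minimal stand-in for telomere degeneracy, sub-telomeric and
  interstitial telomere-like sequence, and sequencing artifacts. The
  generating allele label is recorded per unit regardless of overwrites.

* :func:`simulate_wgs_reads` draws 150 bp reads from the array on either
  strand, with substitution errors at a low head rate and a higher tail
  rate past the trim point (emulating the quality decay of real telomeric
  reads) and quality strings encoding the generating rates.

* :func:`simulate_terminal_reads` emits reverse reads that start at the
  C-tail: an optional adapter-like prefix, a G-run (the tail complement),
  then the reverse complement of the chromosome's 3' terminus in a chosen
  repeat register. Junk reads violating each of the three terminal
  quality filters can be mixed in.

All randomness flows from the explicit ``seed`` arguments; identical seeds
give byte-identical FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .composition import greedy_scan
from .records import ReadRecord, reverse_complement
from .terminal import CTAIL_MOTIFS, VAR_ROTATIONS, WT_ROTATIONS

WT_HEXAMER = "TTAGGG"
VAR_HEXAMER = "TTAGGT"

_BASES = "ACGT"
_ROTATION_SET = frozenset(WT_ROTATIONS) | frozenset(VAR_ROTATIONS)


def _check_probability(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value!r}")


@dataclass(frozen=True)
class ModelParams:
    """Two-allele re-association model parameters.

    ``p_x_wt`` / ``p_x_var`` are the processive-continuation probabilities
    of the wild-type- and variant-template enzymes; ``rho`` is the chance
    a re-associating enzyme carries the variant template (0.5 under equal
    allele expression); ``degeneracy`` is the per-unit chance a deposited
    hexamer is overwritten by a random non-canonical hexamer (~0.15 in
    real telomeric WGS sequence).
    """

    p_x_wt: float = 0.91
    p_x_var: float = 0.39
    rho: float = 0.5
    degeneracy: float = 0.15

    def __post_init__(self) -> None:
        for name in ("p_x_wt", "p_x_var", "rho", "degeneracy"):
            _check_probability(name, getattr(self, name))


@dataclass
class TelomereArray:
    """A simulated telomere: hexamer units plus per-unit ground truth."""

    hexamers: List[str]
    alleles: List[str]  # generating template per unit: "wt" or "var"

    @property
    def sequence(self) -> str:
        return "".join(self.hexamers)

    @property
    def n_units(self) -> int:
        return len(self.hexamers)

    def unit_classes(self) -> List[str]:
        """Observed class per unit: wt / var / other (after degeneracy)."""
        lookup = {WT_HEXAMER: "wt", VAR_HEXAMER: "var"}
        return [lookup.get(h, "other") for h in self.hexamers]

    def write_truth(self, path) -> None:
        """Sidecar TSV of ground truth: unit index, hexamer, allele label."""
        with open(path, "w") as handle:
            handle.write("unit_index\thexamer\tallele\n")
            for i, (h, a) in enumerate(zip(self.hexamers, self.alleles)):
                handle.write(f"{i}\t{h}\t{a}\n")


def _random_other_hexamer(rng: np.random.Generator) -> str:
    while True:
        hexamer = "".join(_BASES[b] for b in rng.integers(0, 4, size=6))
        if hexamer not in (WT_HEXAMER, VAR_HEXAMER):
            return hexamer


def simulate_telomere_array(
    params: ModelParams, n_units: int, seed: int
) -> TelomereArray:
    """Grow a telomere of ``n_units`` hexamers under the re-association model.

    The first unit's allele is drawn like a re-association event (variant
    with probability ``rho``). Each later unit continues the previous
    allele with that allele's ``p_x``, otherwise re-associates. Degeneracy
    then overwrites the deposited hexamer; the allele label keeps the
    generating template.
    """
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    rng = np.random.default_rng(seed)
    p_x = {"wt": params.p_x_wt, "var": params.p_x_var}
    u_cont = rng.random(n_units).tolist()
    u_assoc = rng.random(n_units).tolist()
    u_degen = rng.random(n_units).tolist()

    hexamers: List[str] = []
    alleles: List[str] = []
    allele = "var" if u_assoc[0] < params.rho else "wt"
    for i in range(n_units):
        if i > 0:
            if u_cont[i] >= p_x[allele]:  # dissociation, then re-association
                allele = "var" if u_assoc[i] < params.rho else "wt"
        unit = VAR_HEXAMER if allele == "var" else WT_HEXAMER
        if u_degen[i] < params.degeneracy:
            unit = _random_other_hexamer(rng)
        hexamers.append(unit)
        alleles.append(allele)
    return TelomereArray(hexamers, alleles)


def _quality_for_rate(rate: float) -> int:
    if rate <= 0:
        return 40
    return int(min(40, max(2, round(-10.0 * math.log10(rate)))))


@dataclass(frozen=True)
class ReadSimParams:
    """WGS-like read simulation parameters.

    Substitution errors are applied at ``error_rate_head`` for read
    positions up to ``trim_point`` and at the (no smaller)
    ``error_rate_tail`` beyond it; quality strings encode the Phred score
    of the generating rate. With ``frame_aligned`` (default) read starts
    fall on hexamer-unit boundaries, so recovered composition fractions
    estimate the array composition without frame-truncation bias; set it
    False for base-uniform starts as in real libraries.
    """

    read_length: int = 150
    n_reads: int = 10_000
    error_rate_head: float = 0.001
    error_rate_tail: float = 0.02
    trim_point: int = 60
    background_fraction: float = 0.0
    frame_aligned: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _check_probability("error_rate_head", self.error_rate_head)
        _check_probability("error_rate_tail", self.error_rate_tail)
        _check_probability("background_fraction", self.background_fraction)
        if self.error_rate_tail < self.error_rate_head:
            raise ValueError("error_rate_tail must be >= error_rate_head")
        if self.read_length < 1 or self.n_reads < 0:
            raise ValueError("read_length must be >= 1 and n_reads >= 0")


def _apply_errors(
    seq: str, rates: np.ndarray, rng: np.random.Generator
) -> str:
    u = rng.random(len(seq))
    hits = np.nonzero(u < rates)[0]
    if hits.size == 0:
        return seq
    chars = list(seq)
    for pos in hits:
        original = chars[pos]
        choices = [b for b in _BASES if b != original]
        chars[pos] = choices[int(rng.integers(0, len(choices)))]
    return "".join(chars)


def simulate_wgs_reads(
    array: TelomereArray, params: ReadSimParams = ReadSimParams()
) -> List[ReadRecord]:
    """Draw WGS-like reads from a telomere array.

    Each read is sampled uniformly over the array (or, with probability
    ``background_fraction``, is random non-telomeric sequence), emitted on
    the G or C strand with probability 0.5, and subjected to positional
    substitution errors. Read ids record the source start and strand
    (``start=-1`` for background) so mismatches can be audited against the
    known source coordinates.
    """
    sequence = array.sequence
    L = params.read_length
    if len(sequence) < L:
        raise ValueError(
            f"array has {len(sequence)} bases; need at least read_length={L}"
        )
    rng = np.random.default_rng(params.seed)
    rates = np.where(
        np.arange(L) < params.trim_point,
        params.error_rate_head,
        params.error_rate_tail,
    )
    qualities = tuple(
        _quality_for_rate(params.error_rate_head if p < params.trim_point else params.error_rate_tail)
        for p in range(L)
    )
    n_start_units = (len(sequence) - L) // 6 + 1
    reads: List[ReadRecord] = []
    for i in range(params.n_reads):
        if rng.random() < params.background_fraction:
            seq = "".join(_BASES[b] for b in rng.integers(0, 4, size=L))
            start, label = -1, "bg"
        else:
            if params.frame_aligned:
                start = 6 * int(rng.integers(0, n_start_units))
            else:
                start = int(rng.integers(0, len(sequence) - L + 1))
            seq = sequence[start : start + L]
            label = "tel"
        strand = "-" if rng.random() < 0.5 else "+"
        if strand == "-":
            seq = reverse_complement(seq)
        seq = _apply_errors(seq, rates, rng)
        reads.append(
            ReadRecord(f"{label}_{i}|start={start}|strand={strand}", seq, qualities)
        )
    return reads


@dataclass(frozen=True)
class TerminalSimParams:
    """C-tail terminal-read simulation parameters.

    ``permutation_weights`` maps each terminal register (12 rotations plus
    ``"other"``) to its probability; ``tail_lengths`` is a distribution
    over C-tail length (>= 6). ``junk_fraction`` of reads are constructed
    to violate one of the three terminal quality filters.
    """

    permutation_weights: Dict[str, float] = field(
        default_factory=lambda: {
            # wild-type termini dominate and favor the -GGTTAG register;
            # variant termini favor -GGTTTA.
            "GGTTAG": 0.50,
            "GTTAGG": 0.06,
            "TTAGGG": 0.06,
            "TAGGGT": 0.06,
            "AGGGTT": 0.06,
            "GGGTTA": 0.06,
            "GGTTTA": 0.10,
            "GTTTAG": 0.016,
            "TTTAGG": 0.016,
            "TTAGGT": 0.016,
            "TAGGTT": 0.016,
            "AGGTTT": 0.016,
            "other": 0.02,
        }
    )
    tail_lengths: Dict[int, float] = field(
        default_factory=lambda: {n: 1.0 / 9.0 for n in range(7, 16)}
    )
    n_reads: int = 10_000
    junk_fraction: float = 0.0
    read_length: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.permutation_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"permutation_weights must sum to 1 (got {total!r})"
            )
        for key in self.permutation_weights:
            if key != "other" and key not in _ROTATION_SET:
                raise ValueError(f"unknown terminal permutation {key!r}")
        if any(w < 0 for w in self.permutation_weights.values()):
            raise ValueError("permutation_weights must be non-negative")
        tail_total = sum(self.tail_lengths.values())
        if abs(tail_total - 1.0) > 1e-9:
            raise ValueError("tail_lengths must sum to 1")
        if any(n < 6 for n in self.tail_lengths):
            raise ValueError("C-tail lengths must be >= 6")
        _check_probability("junk_fraction", self.junk_fraction)


def _random_nong_prefix(rng: np.random.Generator, length: int) -> str:
    # adapter-like filler; no G so it can never extend or create a G-run
    return "".join("ACT"[b] for b in rng.integers(0, 3, size=length))


def _random_non_rotation_hexamer(rng: np.random.Generator) -> str:
    while True:
        hexamer = "".join(_BASES[b] for b in rng.integers(0, 4, size=6))
        if hexamer not in _ROTATION_SET:
            return hexamer


def _weighted_choice(rng: np.random.Generator, weights: Dict) -> object:
    keys = sorted(weights)  # stable order => reproducible draws
    probs = np.array([weights[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _terminal_read_bases(
    rng: np.random.Generator,
    perm: str,
    tail_len: int,
    read_length: int,
    g_run_override: Optional[int] = None,
) -> str:
    prefix = _random_nong_prefix(rng, int(rng.integers(0, 13)))
    g_len = tail_len if g_run_override is None else g_run_override
    if perm == "other":
        terminal = _random_non_rotation_hexamer(rng)
        unit = "GGTTAG"
    else:
        terminal = perm
        unit = perm
    needed = read_length - len(prefix) - g_len - 6
    inner = (reverse_complement(unit) * (needed // 6 + 2))[:needed]
    return prefix + "G" * g_len + reverse_complement(terminal) + inner


def _junk_read_bases(
    rng: np.random.Generator, kind: str, tail_len: int, read_length: int
) -> str:
    if kind == "ctail_motifs":
        # random sequence: ~never reaches 5 C-tail motifs; G-run present so
        # only the motif criterion fails
        while True:
            body = "".join(_BASES[b] for b in rng.integers(0, 4, size=read_length - 8))
            bases = body[:20] + "G" * 8 + body[20:]
            if len(greedy_scan(bases, CTAIL_MOTIFS)) < 5:
                return bases
    if kind == "g_run":
        # valid telomeric structure but the tail run is capped at 5 Gs
        return _terminal_read_bases(rng, "GGTTAG", tail_len, read_length, g_run_override=5)
    if kind == "window":
        bases = _terminal_read_bases(rng, "GGTTAG", tail_len, read_length)
        g_end = bases.index("G" * tail_len) + tail_len
        pos = g_end + int(rng.integers(0, 12))
        return bases[:pos] + "N" + bases[pos + 1 :]
    raise ValueError(f"unknown junk kind {kind!r}")


def simulate_terminal_reads(
    params: TerminalSimParams = TerminalSimParams(),
) -> List[ReadRecord]:
    """Simulate C-tail-anchored reverse reads of telomere termini.

    Passing reads have the structure ``[adapter-like prefix][G-run of the
    drawn tail length][reverse complement of (>=5 telomeric hexamers +
    terminal hexamer)]``; junk reads each violate exactly one constructed
    filter criterion, recorded in the read id.
    """
    rng = np.random.default_rng(params.seed)
    qualities_cache: Dict[int, Tuple[int, ...]] = {}
    reads: List[ReadRecord] = []
    junk_kinds = ("ctail_motifs", "g_run", "window")
    for i in range(params.n_reads):
        tail_len = int(_weighted_choice(rng, params.tail_lengths))
        if rng.random() < params.junk_fraction:
            kind = junk_kinds[int(rng.integers(0, 3))]
            bases = _junk_read_bases(rng, kind, tail_len, params.read_length)
            read_id = f"junk_{i}|reason={kind}"
        else:
            perm = str(_weighted_choice(rng, params.permutation_weights))
            bases = _terminal_read_bases(rng, perm, tail_len, params.read_length)
            read_id = f"term_{i}|perm={perm}|tail={tail_len}"
        n = len(bases)
        if n not in qualities_cache:
            qualities_cache[n] = tuple([37] * n)
        reads.append(ReadRecord(read_id, bases, qualities_cache[n]))
    return reads
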