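"""3' telomere-terminal permutation classification from C-tailed reads.

C-tailing appends cytosines to the single-stranded 3' G-overhang of each
chromosome so the very last telomeric bases can be primed and sequenced.
On the reverse read (which starts at the tail) the C-tail appears as a run
of Gs, followed by the reverse complement of the chromosome's 3' terminus:
the base immediately after the G-run is the complement of the 3'-terminal
nucleotide.

Reads are quality-filtered by three criteria: at least ``min_ctail_motifs``
combined non-overlapping CTAACC/CTAAAC occurrences (telomere-complement
content), a run of at least ``min_g_run`` consecutive Gs (the tail), and
no undefined bases in the ``defined_window`` bases right after the first
such run. The window is reverse-complemented into G-strand orientation
(3' terminus rightmost) and the terminal hexamer is matched exactly
against the six cyclic rotations of TTAGGG (wild type) and of TTAGGT
(variant); anything else is "other".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Tuple

from .composition import greedy_scan
from .records import ReadRecord, reverse_complement


def _rotations(hexamer: str) -> Tuple[str, ...]:
    return tuple(hexamer[i:] + hexamer[:i] for i in range(len(hexamer)))


#: The six cyclic rotations (terminal registers) of each repeat.
WT_ROTATIONS: Tuple[str, ...] = _rotations("TTAGGG")
VAR_ROTATIONS: Tuple[str, ...] = _rotations("TTAGGT")

_WT_SET = frozenset(WT_ROTATIONS)
_VAR_SET = frozenset(VAR_ROTATIONS)

# The two rotation sets must be disjoint or classification is ambiguous.
assert not (_WT_SET & _VAR_SET), "wild-type and variant rotation sets overlap"
assert len(_WT_SET) == 6 and len(_VAR_SET) == 6

#: C-tail filter motifs: reverse complements of GGTTAG (wt) and GTTTAG (var).
CTAIL_MOTIFS: Tuple[str, ...] = ("CTAACC", "CTAAAC")


@dataclass(frozen=True)
class TerminalFilterConfig:
    """Quality filters for C-tail-anchored terminal reads."""

    min_ctail_motifs: int = 5
    min_g_run: int = 6
    defined_window: int = 12

    def __post_init__(self) -> None:
        for name in ("min_ctail_motifs", "min_g_run", "defined_window"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def locate_g_run(read: ReadRecord, min_g_run: int = 6) -> Optional[Tuple[int, int]]:
    """First maximal run of >= ``min_g_run`` consecutive Gs.

    Returns 0-based ``(start, length)``; ``None`` if no qualifying run
    exists. "First" is the smallest start coordinate — with sequencing
    errors splitting the tail there may be several runs, and the first is
    the one nearest the read start where the C-tail complement lies.
    """
    bases = read.bases
    i = 0
    n = len(bases)
    while i < n:
        if bases[i] == "G":
            j = i
            while j < n and bases[j] == "G":
                j += 1
            if j - i >= min_g_run:
                return i, j - i
            i = j
        else:
            i += 1
    return None


def filter_terminal_read(
    read: ReadRecord, config: TerminalFilterConfig = TerminalFilterConfig()
) -> Tuple[bool, Optional[str]]:
    """Apply the three terminal-read quality filters.

    Returns ``(True, None)`` on pass, else ``(False, reason)`` where
    ``reason`` is the first violated criterion: ``"ctail_motifs"``,
    ``"g_run"``, or ``"window"``.
    """
    n_motifs = len(greedy_scan(read.bases, CTAIL_MOTIFS))
    if n_motifs < config.min_ctail_motifs:
        return False, "ctail_motifs"
    run = locate_g_run(read, config.min_g_run)
    if run is None:
        return False, "g_run"
    start, length = run
    window = read.bases[start + length : start + length + config.defined_window]
    if len(window) < config.defined_window or "N" in window:
        return False, "window"
    return True, None


def extract_terminal(
    read: ReadRecord, g_run: Tuple[int, int], window: int = 12
) -> str:
    """G-strand-oriented terminal sequence after the C-tail G-run.

    The ``window`` bases immediately following the G-run are the
    complement-strand copy of the chromosome's 3' terminus; their reverse
    complement is returned with the 3'-terminal nucleotide rightmost.
    """
    start, length = g_run
    chunk = read.bases[start + length : start + length + window]
    if len(chunk) < window:
        raise ValueError(
            f"read {read.read_id!r}: only {len(chunk)} bases after the G-run, "
            f"need {window}"
        )
    return reverse_complement(chunk)


def classify_terminal(terminal_12mer: str) -> Tuple[str, str]:
    """Classify a G-strand terminal 12-mer by its last hexamer.

    Returns ``(repeat_class, permutation_label)`` where the class is
    ``"wt"`` or ``"var"`` if the terminal hexamer is a cyclic rotation of
    TTAGGG or TTAGGT respectively, else ``("other", <hexamer>)``.
    """
    hexamer = terminal_12mer[-6:]
    if hexamer in _WT_SET:
        return "wt", hexamer
    if hexamer in _VAR_SET:
        return "var", hexamer
    return "other", hexamer


@dataclass
class TerminalCall:
    """A classified telomere terminus from one passing read."""

    read_id: str
    g_run_start: int
    g_run_length: int
    terminal_12mer: str
    terminal_hexamer: str
    repeat_class: str
    permutation_label: str


@dataclass
class PermutationSpectrum:
    """Counts of terminal permutations among passing reads.

    ``counts`` covers the 12 rotations; termini matching neither set fall
    into ``other_count``. ``rejections`` tallies reads dropped per filter
    criterion.
    """

    counts: Dict[str, int] = field(
        default_factory=lambda: {r: 0 for r in WT_ROTATIONS + VAR_ROTATIONS}
    )
    other_count: int = 0
    n_reads_total: int = 0
    n_passing: int = 0
    rejections: Dict[str, int] = field(
        default_factory=lambda: {"ctail_motifs": 0, "g_run": 0, "window": 0}
    )

    def class_counts(self) -> Dict[str, int]:
        return {
            "wt": sum(self.counts[r] for r in WT_ROTATIONS),
            "var": sum(self.counts[r] for r in VAR_ROTATIONS),
            "other": self.other_count,
        }

    def class_fractions(self) -> Dict[str, Optional[float]]:
        """Fraction of telomere ends terminating in each class."""
        totals = self.class_counts()
        denom = sum(totals.values())
        if denom == 0:
            return {k: None for k in totals}
        return {k: v / denom for k, v in totals.items()}

    def within_class_fractions(self) -> Dict[str, Dict[str, float]]:
        """Each permutation as a fraction of its class's telomere ends."""
        out: Dict[str, Dict[str, float]] = {}
        for cls, rotations in (("wt", WT_ROTATIONS), ("var", VAR_ROTATIONS)):
            total = sum(self.counts[r] for r in rotations)
            if total:
                out[cls] = {r: self.counts[r] / total for r in rotations}
        return out

    def overall_fractions(self) -> Dict[str, Optional[float]]:
        """Each permutation as a fraction of all passing reads."""
        if self.n_passing == 0:
            return {r: None for r in self.counts}
        return {r: c / self.n_passing for r, c in self.counts.items()}


def call_terminal_read(
    read: ReadRecord, config: TerminalFilterConfig = TerminalFilterConfig()
) -> Optional[TerminalCall]:
    """Filter, locate, extract and classify one read; None if filtered out."""
    ok, _ = filter_terminal_read(read, config)
    if not ok:
        return None
    g_run = locate_g_run(read, config.min_g_run)
    assert g_run is not None
    twelve = extract_terminal(read, g_run, config.defined_window)
    repeat_class, label = classify_terminal(twelve)
    return TerminalCall(
        read_id=read.read_id,
        g_run_start=g_run[0],
        g_run_length=g_run[1],
        terminal_12mer=twelve,
        terminal_hexamer=twelve[-6:],
        repeat_class=repeat_class,
        permutation_label=label,
    )


def spectrum(
    reads: Iterable[ReadRecord], config: TerminalFilterConfig = TerminalFilterConfig()
) -> PermutationSpectrum:
    """Tabulate the terminal-permutation spectrum of a read stream."""
    spec = PermutationSpectrum()
    for read in reads:
        spec.n_reads_total += 1
        ok, reason = filter_terminal_read(read, config)
        if not ok:
            assert reason is not None
            spec.rejections[reason] += 1
            continue
        call = call_terminal_read(read, config)
        assert call is not None
        spec.n_passing += 1
        if call.repeat_class == "other":
            spec.other_count += 1
        else:
            spec.counts[call.permutation_label] += 1
    return spec
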