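"""Sequence databases of discrete gene-change events and the SPMF format.

Each subject becomes one sequence: an ordered list of itemsets, one per
mining interval.  An item is an integer code ``state * 10**w + probe_index``
(w = index width, 4 by default), where state 2 means up-regulation and 1
down-regulation — e.g. code 2001 at width 3 is "probe #1 went up".
No-change events (state 0) are never emitted; positions with no event are
kept as empty itemsets so ordering information and the sequence count |SD|
stay honest.

Probe indices are assigned once per run by a stable lexicographic sort of
probe ids and persisted in a sidecar TSV ``code_index, probe_id, gene`` so
item codes are reproducible across stages and comparable across groups.

The on-disk format is the SPMF text dialect: items space-separated within an
itemset, ``-1`` ends an itemset, ``-2`` ends a sequence; an empty itemset is
a bare ``-1``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .data_model import RuleItem
from .preprocess import DiscreteMatrix

__all__ = [
    "encode_item",
    "decode_item",
    "Codebook",
    "SequenceDatabase",
    "build_codebook",
    "build_sequence_db",
    "write_spmf",
    "read_spmf",
]

DEFAULT_WIDTH = 4


def encode_item(state: int, probe_index: int, width: int = DEFAULT_WIDTH) -> int:
    """Pack (state, probe_index) into a single integer code."""
    if state not in (1, 2):
        raise ValueError("state must be 1 (down) or 2 (up)")
    if not 0 <= probe_index < 10 ** width:
        raise ValueError(
            f"probe index {probe_index} overflows width {width} "
            f"(must be < {10 ** width})"
        )
    return state * 10 ** width + probe_index


def decode_item(code: int, width: int = DEFAULT_WIDTH) -> tuple[int, int]:
    """Inverse of :func:`encode_item`: code -> (state, probe_index)."""
    state, probe_index = divmod(code, 10 ** width)
    if state not in (1, 2):
        raise ValueError(f"item code {code} has invalid state digit {state}")
    return state, probe_index


@dataclass
class Codebook:
    """Stable probe_id <-> probe_index assignment with gene symbols."""

    probe_ids: list[str]
    genes: dict[str, str | None] = field(default_factory=dict)
    width: int = DEFAULT_WIDTH

    def __post_init__(self) -> None:
        self._index = {p: i for i, p in enumerate(self.probe_ids)}
        if len(self._index) != len(self.probe_ids):
            raise ValueError("duplicate probe ids in codebook")
        if len(self.probe_ids) > 10 ** self.width:
            needed = self.width
            while len(self.probe_ids) > 10 ** needed:
                needed += 1
            warnings.warn(
                f"{len(self.probe_ids)} probes overflow item width "
                f"{self.width}; widening to {needed}"
            )
            self.width = needed

    def index_of(self, probe_id: str) -> int:
        return self._index[probe_id]

    def encode(self, state: int, probe_id: str) -> int:
        return encode_item(state, self._index[probe_id], self.width)

    def decode(self, code: int) -> RuleItem:
        state, idx = decode_item(code, self.width)
        probe = self.probe_ids[idx]
        return RuleItem(probe=probe, state=state, gene=self.genes.get(probe))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("code_index\tprobe_id\tgene\n")
            for i, p in enumerate(self.probe_ids):
                fh.write(f"{i}\t{p}\t{self.genes.get(p) or ''}\n")

    @classmethod
    def read(cls, path, width: int = DEFAULT_WIDTH) -> "Codebook":
        df = pd.read_csv(path, sep="\t", dtype=str)
        order = df.sort_values("code_index", key=lambda s: s.astype(int))
        probe_ids = list(order["probe_id"])
        genes = {p: (g if isinstance(g, str) and g else None)
                 for p, g in zip(order["probe_id"], order["gene"])}
        return cls(probe_ids=probe_ids, genes=genes, width=width)


@dataclass
class SequenceDatabase:
    """Per-subject ordered itemsets of discrete events for one group.

    ``sequences[j]`` is the ordered list of (frozen) integer itemsets for
    subject ``subject_ids[j]``; |SD| = number of sequences = number of
    subjects.  ``codebook`` (optional) maps codes back to probes/genes.
    """

    group: str
    sequences: list[list[frozenset[int]]]
    subject_ids: list[str] | None = None
    codebook: Codebook | None = None

    def __post_init__(self) -> None:
        # databases built from a discrete matrix have one itemset per
        # mining interval for every subject; generic SPMF input may be
        # ragged, so equal length is only enforced for subject-built DBs
        if self.subject_ids is not None:
            lengths = {len(s) for s in self.sequences}
            if len(lengths) > 1:
                raise ValueError("all subject sequences must have the same "
                                 "number of itemsets (one per interval)")
        if self.subject_ids is not None and \
                len(self.subject_ids) != len(self.sequences):
            raise ValueError("subject_ids length mismatch")

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def n_itemsets(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def item_universe(self) -> set[int]:
        return {it for seq in self.sequences for iset in seq for it in iset}

    def item(self, code: int) -> RuleItem:
        if self.codebook is not None:
            return self.codebook.decode(code)
        # no codebook: expose the raw code as the probe name
        state, _ = decode_item(code, _infer_width(code))
        return RuleItem(probe=str(code), state=state, gene=None)


def _infer_width(code: int) -> int:
    return max(1, len(str(code)) - 1)


def build_codebook(discrete_by_group: dict[str, DiscreteMatrix],
                   width: int = DEFAULT_WIDTH) -> Codebook:
    """One shared codebook over every probe carrying at least one event in
    any group (lexicographic probe order), so groups are contrast-comparable."""
    probes: set[str] = set()
    genes: dict[str, str | None] = {}
    for dm in discrete_by_group.values():
        for tab in dm.states.values():
            nonzero = tab.index[(tab != 0).any(axis=1)]
            probes.update(nonzero)
        genes.update(dm.probe_genes)
    ordered = sorted(probes)
    return Codebook(probe_ids=ordered,
                    genes={p: genes.get(p) for p in ordered}, width=width)


def build_sequence_db(discrete: DiscreteMatrix, group: str,
                      codebook: Codebook | None = None) -> SequenceDatabase:
    """Build the sequence database for one group from its discrete states,
    using the mining intervals only (selection-only intervals overlap them)."""
    if group not in discrete.group_names():
        raise KeyError(f"group {group!r} absent from discrete matrix")
    if codebook is None:
        codebook = build_codebook({group: discrete})
    mining = discrete.intervals.mining
    subjects = [s for s, g in discrete.groups.items() if g == group]
    sequences: list[list[frozenset[int]]] = []
    for subject in subjects:
        seq = []
        for iv in mining:
            tab = discrete.table(iv.label, group)
            col = tab[subject]
            items = frozenset(
                codebook.encode(int(state), probe)
                for probe, state in col.items() if state != 0
            )
            seq.append(items)
        sequences.append(seq)
    return SequenceDatabase(group=group, sequences=sequences,
                            subject_ids=subjects, codebook=codebook)


def write_spmf(seqdb: SequenceDatabase, path) -> None:
    """Write the SPMF text dialect; items within an itemset are emitted in
    sorted order for deterministic files."""
    with open(path, "w") as fh:
        for seq in seqdb.sequences:
            tokens: list[str] = []
            for iset in seq:
                tokens.extend(str(i) for i in sorted(iset))
                tokens.append("-1")
            tokens.append("-2")
            fh.write(" ".join(tokens) + "\n")


def read_spmf(path, group: str = "", codebook: Codebook | None = None
              ) -> SequenceDatabase:
    """Parse an SPMF sequence file.  Every sequence must be terminated by
    ``-2``; a bare ``-1`` is an empty itemset."""
    sequences: list[list[frozenset[int]]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            try:
                tokens = [int(tok) for tok in line.split()]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token") from exc
            if tokens[-1] != -2:
                raise ValueError(f"{path}:{lineno}: sequence not ended by -2")
            if tokens.count(-2) != 1:
                raise ValueError(f"{path}:{lineno}: multiple -2 terminators")
            seq: list[frozenset[int]] = []
            current: set[int] = set()
            for tok in tokens[:-1]:
                if tok == -1:
                    seq.append(frozenset(current))
                    current = set()
                elif tok < 0:
                    raise ValueError(f"{path}:{lineno}: invalid token {tok}")
                else:
                    current.add(tok)
            if current:
                raise ValueError(
                    f"{path}:{lineno}: trailing items not closed by -1"
                )
            sequences.append(seq)
    return SequenceDatabase(group=group, sequences=sequences,
                            codebook=codebook)
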