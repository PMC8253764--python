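"""Reading, validating and symbolizing ethogram event data.

An *ethogram* is a time-log of discrete, objectively defined behavioral
events.  Each event carries a code drawn from a closed terminal alphabet,
an onset time and a duration.  Downstream grammar analysis discards the
timing and works on the time-scale-invariant symbol sequence.

The default alphabet covers the seven elementary actions of stone-tool
knapping (percussion, target change, core/tool grip shifts, core
inversion, flake detachment, tool change); any behavioral domain can
substitute its own :class:`EventAlphabet`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "EventAlphabet",
    "EventRecord",
    "Ethogram",
    "SymbolSequence",
    "DEFAULT_ALPHABET",
    "DEFAULT_ALIASES",
    "read_ethogram",
    "write_ethogram",
    "to_symbols",
    "collapse_runs",
    "read_symbol_file",
    "write_symbol_file",
    "read_alphabet",
    "write_alphabet",
]


@dataclass(frozen=True)
class EventAlphabet:
    """Closed, ordered set of terminal event codes.

    The order of ``entries`` is fixed and defines the column order of HMM
    emission matrices.  Codes must be unique, non-empty tokens; at least
    two are required for any sequence analysis to be meaningful.
    """

    entries: tuple[tuple[str, str, str], ...]  # (code, label, description)

    def __post_init__(self) -> None:
        codes = [c for c, _, _ in self.entries]
        if len(codes) < 2:
            raise ValueError("alphabet needs at least 2 entries")
        if any(not c for c in codes):
            raise ValueError("alphabet codes must be non-empty")
        if len(set(codes)) != len(codes):
            raise ValueError("alphabet codes must be unique")

    @property
    def codes(self) -> tuple[str, ...]:
        return tuple(c for c, _, _ in self.entries)

    @property
    def labels(self) -> dict[str, str]:
        return {c: l for c, l, _ in self.entries}

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, code: object) -> bool:
        return code in self.codes

    def index(self, code: str) -> int:
        """Column index of ``code`` in emission-matrix order."""
        try:
            return self.codes.index(code)
        except ValueError:
            raise KeyError(f"code {code!r} not in alphabet {self.codes}") from None

    def encode(self, symbols: Sequence[str]) -> list[int]:
        return [self.index(s) for s in symbols]

    def decode(self, indices: Sequence[int]) -> list[str]:
        codes = self.codes
        return [codes[i] for i in indices]


#: Seven elementary knapping actions.  Mnemonic single-letter codes.
DEFAULT_ALPHABET = EventAlphabet(
    entries=(
        ("P", "Percussion", "Striking core with percussor"),
        ("T", "TargetChange", "Change in the location of percussion on the core"),
        ("G", "GripShiftCore", "Repositioning of the hand grasping the core"),
        ("H", "GripShiftTool", "Repositioning of the hand grasping the percussor"),
        ("I", "Inversion", "Flipping over the core without otherwise reorienting"),
        ("F", "FlakeDetach", "Removal of a flake > 20 mm"),
        ("X", "ToolChange", "Exchange of one percussor for another"),
    )
)

#: Input-code aliases applied before validation.  Light percussion is not a
#: distinct terminal: it is folded into ordinary percussion.
DEFAULT_ALIASES: dict[str, str] = {"L": "P", "LP": "P", "LightPercussion": "P"}


@dataclass(frozen=True)
class EventRecord:
    """One coded event: alphabet code, onset and duration in seconds."""

    code: str
    onset: float
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.onset < 0 or self.duration < 0:
            raise ValueError("onset and duration must be >= 0")


@dataclass(frozen=True)
class Ethogram:
    """One coded behavioral sequence with timing, onset-sorted."""

    sequence_id: str
    category: str
    records: tuple[EventRecord, ...]


@dataclass(frozen=True)
class SymbolSequence:
    """Ordered terminal symbols of one sequence; the unit of analysis."""

    sequence_id: str
    category: str
    symbols: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"sequence {self.sequence_id!r} is empty")

    def __len__(self) -> int:
        return len(self.symbols)

    def validate(self, alphabet: EventAlphabet) -> None:
        bad = sorted({s for s in self.symbols if s not in alphabet})
        if bad:
            raise ValueError(
                f"sequence {self.sequence_id!r} contains codes {bad} "
                f"not in alphabet {alphabet.codes}"
            )


_CSV_COLUMNS = ["sequence_id", "category", "code", "onset_s", "duration_s"]


def _apply_aliases(code: str, aliases: Mapping[str, str] | None) -> str:
    if aliases:
        return aliases.get(code, code)
    return code


def read_ethogram(
    path: str | Path,
    alphabet: EventAlphabet = DEFAULT_ALPHABET,
    aliases: Mapping[str, str] | None = None,
) -> list[Ethogram]:
    """Read an ethogram CSV into one :class:`Ethogram` per sequence id.

    The CSV must carry the header columns
    ``sequence_id, category, code, onset_s, duration_s``.  Codes are passed
    through the ``aliases`` table (e.g. mapping a light-percussion code to
    plain percussion) before validation against the alphabet.  Records are
    sorted by onset (stable, so file order breaks ties); non-monotone
    onsets in the file produce a warning, unknown codes an error naming
    the offending row.
    """
    df = pd.read_csv(path, dtype={"sequence_id": str, "category": str, "code": str})
    if df.empty:
        raise ValueError(f"ethogram file {path} contains no event rows")
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"ethogram file {path} missing columns {missing}")

    df = df.copy()
    df["code"] = [_apply_aliases(c, aliases) for c in df["code"]]
    unknown = df.loc[~df["code"].isin(alphabet.codes)]
    if not unknown.empty:
        row = unknown.index[0]
        codes = sorted(unknown["code"].unique())
        raise ValueError(
            f"unknown event code(s) {codes} (first at data row {row}); "
            f"alphabet is {alphabet.codes}"
        )

    out: list[Ethogram] = []
    for seq_id, grp in df.groupby("sequence_id", sort=False):
        onsets = grp["onset_s"].to_numpy()
        if (onsets[1:] < onsets[:-1]).any():
            warnings.warn(
                f"sequence {seq_id!r}: onsets not monotone in file; sorting",
                stacklevel=2,
            )
        grp = grp.sort_values("onset_s", kind="stable")
        cats = grp["category"].unique()
        if len(cats) > 1:
            raise ValueError(f"sequence {seq_id!r} has conflicting categories {list(cats)}")
        records = tuple(
            EventRecord(code=r.code, onset=float(r.onset_s), duration=float(r.duration_s))
            for r in grp.itertuples()
        )
        out.append(Ethogram(sequence_id=str(seq_id), category=str(cats[0]), records=records))
    return out


def write_ethogram(ethograms: Iterable[Ethogram], path: str | Path) -> None:
    """Write ethograms back to the CSV layout read by :func:`read_ethogram`."""
    rows = [
        {
            "sequence_id": e.sequence_id,
            "category": e.category,
            "code": r.code,
            "onset_s": r.onset,
            "duration_s": r.duration,
        }
        for e in ethograms
        for r in e.records
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def to_symbols(ethogram: Ethogram) -> SymbolSequence:
    """Project an ethogram to its bare symbol sequence (timing discarded)."""
    if not ethogram.records:
        raise ValueError(f"ethogram {ethogram.sequence_id!r} has no records")
    return SymbolSequence(
        sequence_id=ethogram.sequence_id,
        category=ethogram.category,
        symbols=tuple(r.code for r in ethogram.records),
    )


def collapse_runs(seq: SymbolSequence, code: str) -> SymbolSequence:
    """Replace every maximal run of consecutive ``code`` by one occurrence.

    Used to test whether a corpus contrast (e.g. compressibility) is driven
    purely by long repeated runs of a single action, such as the percussion
    runs of striking-platform preparation.  Idempotent.
    """
    out: list[str] = []
    for s in seq.symbols:
        if s == code and out and out[-1] == code:
            continue
        out.append(s)
    return replace(seq, symbols=tuple(out))


def read_symbol_file(
    path: str | Path,
    alphabet: EventAlphabet | None = DEFAULT_ALPHABET,
    category: str = "",
) -> list[SymbolSequence]:
    """Read bare symbol sequences, one per line, whitespace-separated.

    A line may begin with an ``id:category:`` prefix; otherwise sequences
    are numbered ``seq1, seq2, ...`` and assigned ``category``.  Pass
    ``alphabet=None`` to skip validation (e.g. word sequences).
    """
    out: list[SymbolSequence] = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            seq_id, cat = f"seq{len(out) + 1}", category
            head = line.split(None, 1)[0]
            if head.count(":") == 2 and head.endswith(":"):
                seq_id, cat, _ = head.split(":")
                line = line.split(None, 1)[1] if " " in line or "\t" in line else ""
            symbols = tuple(line.split())
            if not symbols:
                raise ValueError(f"{path} line {i}: empty sequence")
            s = SymbolSequence(sequence_id=seq_id, category=cat, symbols=symbols)
            if alphabet is not None:
                s.validate(alphabet)
            out.append(s)
    return out


def write_symbol_file(sequences: Iterable[SymbolSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in sequences:
            fh.write(f"{s.sequence_id}:{s.category}: " + " ".join(s.symbols) + "\n")


def read_alphabet(path: str | Path) -> EventAlphabet:
    """Read an alphabet from a YAML mapping ``code -> label`` (ordered)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"alphabet file {path} must be a YAML mapping code -> label")
    return EventAlphabet(entries=tuple((str(c), str(l), "") for c, l in data.items()))


def write_alphabet(alphabet: EventAlphabet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({c: l for c, l, _ in alphabet.entries}, fh, sort_keys=False)
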