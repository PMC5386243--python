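"""Learning-event file I/O.

An events TSV holds one word token per row with columns Cues (FBS
identifiers joined by "_" — identifiers contain no underscores, so the
join is unambiguous), Outcomes (the word label), Speaker and TokenId.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

EVENT_COLUMNS = ["Cues", "Outcomes", "Speaker", "TokenId"]


@dataclass(frozen=True)
class TokenRecord:
    """One word token as presented to the network."""

    token_id: str
    word: str
    speaker: str
    cues: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cues", frozenset(self.cues))
        if not self.cues:
            raise ValueError(f"token {self.token_id!r} has an empty cue set")


def write_events(path: str | Path, tokens: list[TokenRecord]) -> None:
    rows = [
        {
            "Cues": "_".join(sorted(t.cues)),
            "Outcomes": t.word,
            "Speaker": t.speaker,
            "TokenId": t.token_id,
        }
        for t in tokens
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> list[TokenRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing event column(s): {', '.join(missing)}")
    return [
        TokenRecord(
            token_id=row.TokenId,
            word=row.Outcomes,
            speaker=row.Speaker,
            cues=frozenset(row.Cues.split("_")) if row.Cues else frozenset(),
        )
        for row in df.itertuples(index=False)
    ]
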