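"""Atom-type vocabulary: which elements the model generates and their valencies."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class AtomVocabulary:
    """Ordered element alphabet with allowed valencies.

    The default covers the QM9 element set (H plus the heavy atoms C, N, O,
    F); ``k`` is the one-hot feature dimension of the atom-type matrix.
    """

    symbols: tuple[str, ...] = ("H", "C", "N", "O", "F")
    valencies: dict[str, int] = field(
        default_factory=lambda: {"H": 1, "C": 4, "N": 3, "O": 2, "F": 1}
    )

    def __post_init__(self):
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("vocabulary symbols must be unique")
        for s in self.symbols:
            v = self.valencies.get(s)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"valency of {s!r} must be a positive integer")

    @property
    def k(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"element {symbol!r} not in vocabulary {self.symbols}")

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols

    def valence(self, symbol: str) -> int:
        return self.valencies[symbol]


DEFAULT_VOCABULARY = AtomVocabulary()
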