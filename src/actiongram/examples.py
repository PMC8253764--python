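"""Small built-in example inputs.

``CANONICAL_SENTENCE`` is the classic demonstration input for digram
substitution grammar induction: a word sequence whose repeated phrases
("the little cat", "the mouse", "the big cat") are exactly the rules a
Sequitur-style compressor should discover at k = 2.
"""

from .ethogram_io import SymbolSequence

CANONICAL_SENTENCE = (
    "the little cat chases the mouse "
    "the little cat catches the mouse "
    "the big cat chases the little cat "
    "the little cat runs away from the big cat"
)


def canonical_sentence_sequence() -> SymbolSequence:
    """The demonstration sentence tokenized into a word SymbolSequence."""
    return SymbolSequence(
        sequence_id="canonical",
        category="example",
        symbols=tuple(CANONICAL_SENTENCE.split()),
    )
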