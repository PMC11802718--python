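"""Sliding-window chunking of tokenized notes.

Instruction-tuned encoder-decoder models bound the input at a maximum
sequence length (512 tokens here by default), while clinical notes routinely
run to thousands of tokens.  The standard question-answering remedy is a
sliding window with a document stride: chunk start offsets advance by
``stride`` tokens, each chunk holds up to ``window`` tokens, and the task
prompt is prepended to every chunk so each model input stays within the
maximum length.  With a 50-token prompt and a 512-token budget the window is
462 tokens; the default stride is 128.

The stride is the *advance* between consecutive chunk starts (start +=
stride), not the overlap; consecutive chunks therefore overlap by
``window - stride`` tokens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, Sequence


class ChunkingError(ValueError):
    pass


class TokenizerContract(Protocol):
    """Minimal tokenizer interface the chunker relies on."""

    def tokenize(self, text: str) -> list[str]: ...

    def detokenize(self, tokens: Sequence[str]) -> str: ...


class WhitespaceTokenizer:
    """Backend-free tokenizer: split on whitespace, join with single spaces.

    Token counts under this tokenizer will not match a subword tokenizer's;
    real-model runs should count with the backend's own tokenizer.
    Detokenization preserves every whitespace-delimited term as a substring,
    which is all the downstream string filters require.
    """

    def tokenize(self, text: str) -> list[str]:
        return text.split()

    def detokenize(self, tokens: Sequence[str]) -> str:
        return " ".join(tokens)


@dataclass(frozen=True)
class Chunk:
    """A contiguous token window of a note; offsets are 0-based, end exclusive."""

    start_token: int
    end_token: int
    text: str

    def __len__(self) -> int:
        return self.end_token - self.start_token


def make_chunks(
    note_tokens: Sequence[str],
    window: int,
    stride: int,
    detokenize: Callable[[Sequence[str]], str] = " ".join,
) -> list[Chunk]:
    """Split a token sequence into sliding windows.

    Start offsets are 0, stride, 2*stride, ...; generation stops with the
    first chunk whose end reaches the final token.  A note that fits in one
    window yields exactly one chunk; a final chunk shorter than ``window`` is
    kept, not dropped.  An empty token list yields no chunks (the caller is
    expected to flag the empty note).
    """
    if window < 1:
        raise ChunkingError(f"window must be >= 1, got {window}")
    if not 1 <= stride <= window:
        raise ChunkingError(f"stride must be in [1, window={window}], got {stride}")
    n = len(note_tokens)
    if n == 0:
        return []
    chunks: list[Chunk] = []
    start = 0
    while True:
        end = min(start + window, n)
        chunks.append(Chunk(start, end, detokenize(note_tokens[start:end])))
        if end >= n:
            return chunks
        start += stride


def plan_window(prompt_tokens: Sequence[str], max_len: int = 512) -> int:
    """Chunk window size leaving room for the prompt: max_len - len(prompt)."""
    k = len(prompt_tokens)
    if k >= max_len:
        raise ChunkingError(
            f"prompt of {k} tokens leaves no room in max_len={max_len}"
        )
    return max_len - k

def assemble_input(
    prompt_tokens: Sequence[str],
    chunk: Chunk,
    max_len: int = 512,
    detokenize: Callable[[Sequence[str]], str] = " ".join,
) -> str:
    """Prepend prompt tokens to a chunk, enforcing the length budget."""
    total = len(prompt_tokens) + len(chunk)
    if total > max_len:
        raise ChunkingError(
            f"prompt ({len(prompt_tokens)}) + chunk ({len(chunk)}) = {total} "
            f"exceeds max_len={max_len}; re-chunk with window = "
            f"{max_len - len(prompt_tokens)}"
        )
    prompt_text = detokenize(prompt_tokens)
    if not prompt_text:
        return chunk.text
    if not chunk.text:
        return prompt_text
    return f"{prompt_text} {chunk.text}"
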