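"""Position frequency matrix models of transcription factor binding.

A :class:`Pwm` stores per-position base probabilities for a transcription
factor's binding preference.  Binding affinity of a concrete DNA window is
summarized by the MATCH similarity score: an information-content-weighted
sum of the window's base frequencies, min--max normalized into [0, 1] so
that the motif consensus scores exactly 1 and the per-position least
preferred sequence scores exactly 0.

The erosion statistic of the screen is the *affinity drop*: the relative
decrease in MATCH score when an individual's derived alleles replace the
ancestral (reference) bases inside a binding site window.
"""

from __future__ import annotations

import dataclasses
import io
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# byte -> base code; anything outside ACGT/acgt (N, gaps, ...) maps to -1
_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes (A=0, C=1, G=2, T=3, other=-1)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


class AmbiguousBaseError(ValueError):
    """A scoring window contains a base outside {A, C, G, T}."""


class UnscoreableSiteError(ValueError):
    """Affinity drop is undefined because the reference window scores 0."""


@dataclasses.dataclass
class Pwm:
    """A position frequency matrix over {A, C, G, T}.

    Frequencies are regularized on construction: each row is normalized to
    sum to 1, then ``pseudocount`` probability mass is added to every cell
    and the row renormalized, so log terms in the information vector stay
    finite.  ``pseudocount=0`` is allowed and leaves sharp columns sharp.
    """

    id: str
    tf_name: str
    freqs: np.ndarray  # (L, 4), rows sum to 1 after regularization
    kind: str = "monomer"  # monomer | dimer (dimers arrive pre-concatenated)
    pseudocount: float = 1e-3

    def __post_init__(self) -> None:
        f = np.array(self.freqs, dtype=float)
        if f.ndim != 2 or f.shape[1] != 4 or f.shape[0] < 1:
            raise ValueError(f"PWM {self.id!r}: frequency matrix must be (L>=1, 4)")
        if (f < 0).any():
            raise ValueError(f"PWM {self.id!r}: negative frequencies")
        if self.kind not in ("monomer", "dimer"):
            raise ValueError(f"PWM {self.id!r}: kind must be monomer or dimer")
        row_sums = f.sum(axis=1)
        if not (row_sums > 0).all():
            raise ValueError(f"PWM {self.id!r}: empty frequency row")
        f = f / row_sums[:, None]
        if self.pseudocount > 0:
            f = (f + self.pseudocount) / (1.0 + 4.0 * self.pseudocount)
        self.freqs = f
        # scoring caches
        info = np.where(f > 0, f * np.log(np.where(f > 0, 4.0 * f, 1.0)), 0.0).sum(axis=1)
        self._info = info
        self._weights = info[:, None] * f  # (L, 4)
        self._min_raw = float((info * f.min(axis=1)).sum())
        self._max_raw = float((info * f.max(axis=1)).sum())

    def __len__(self) -> int:
        return self.freqs.shape[0]

    @property
    def consensus(self) -> str:
        """Most frequent base per position (ties: alphabetically first)."""
        return "".join(BASES[i] for i in self.freqs.argmax(axis=1))

    def min_frequency_base(self, position: int) -> str:
        """Least frequent base at ``position`` (ties: alphabetically first)."""
        return BASES[int(self.freqs[position].argmin())]


def information_vector(pwm: Pwm) -> np.ndarray:
    """Per-position information content I(i) = sum_b f(i,b) ln(4 f(i,b)).

    Zero-frequency terms contribute 0.  Entries lie in [0, ln 4]: a uniform
    column carries no information, a deterministic column carries ln 4.
    """
    return pwm._info.copy()


def score_codes(pwm: Pwm, codes: np.ndarray) -> float:
    """MATCH score of an already-encoded window (no ambiguity checking)."""
    raw = float(pwm._weights[np.arange(len(pwm)), codes].sum())
    span = pwm._max_raw - pwm._min_raw
    if span <= 0.0:
        # fully uniform motif: every window is simultaneously consensus
        return 1.0
    return (raw - pwm._min_raw) / span


def match_score(pwm: Pwm, window: str) -> float:
    """MATCH similarity of ``window`` to ``pwm``, in [0, 1].

    score = (Current - Min) / (Max - Min) with
    Current = sum_i I(i) f(i, b_i), Min/Max = sum_i I(i) min_b/max_b f(i, b).

    Raises
    ------
    ValueError
        If the window length differs from the motif length.
    AmbiguousBaseError
        If the window contains a base outside {A, C, G, T}.
    """
    if len(window) != len(pwm):
        raise ValueError(
            f"window length {len(window)} != motif length {len(pwm)} for {pwm.id!r}"
        )
    codes = encode_sequence(window)
    if (codes < 0).any():
        raise AmbiguousBaseError(f"window {window!r} contains non-ACGT bases")
    return score_codes(pwm, codes)


def affinity_drop(
    pwm: Pwm, ref_window: str, alt_window: str, mode: str = "relative"
) -> float:
    """Fractional loss of MATCH score from ``ref_window`` to ``alt_window``.

    ``relative`` (default): (score_ref - score_alt) / score_ref.
    ``absolute``: score_ref - score_alt.

    Negative values indicate an affinity gain.  A reference score of 0 makes
    the relative drop undefined and raises :class:`UnscoreableSiteError`.
    """
    s_ref = match_score(pwm, ref_window)
    s_alt = match_score(pwm, alt_window)
    if mode == "absolute":
        return s_ref - s_alt
    if mode != "relative":
        raise ValueError(f"unknown affinity drop mode {mode!r}")
    if s_ref == 0.0:
        raise UnscoreableSiteError(
            f"reference window {ref_window!r} scores 0 under {pwm.id!r}"
        )
    return (s_ref - s_alt) / s_ref


def reverse_complement(pwm: Pwm) -> Pwm:
    """The PWM scoring the reverse complement strand.

    Column order is reversed and base frequencies complemented (A<->T,
    C<->G).  Applying twice restores the input exactly; the regularized
    frequencies are carried over unchanged (pseudocount 0 on the copy).
    """
    return Pwm(
        id=pwm.id,
        tf_name=pwm.tf_name,
        freqs=pwm.freqs[::-1, ::-1].copy(),
        kind=pwm.kind,
        pseudocount=0.0,
    )


def shuffle_pwm_preserve_cpg(pwm: Pwm, seed: int) -> Pwm:
    """Column-shuffle the motif, keeping consensus CpG dinucleotides intact.

    Adjacent column pairs whose consensus reads C then G are moved as a
    unit (in order); all other columns move independently.  The per-column
    frequency multiset — and hence the maximal attainable raw score — is
    preserved.  Deterministic for a given seed.
    """
    L = len(pwm)
    if L < 2:
        return Pwm(pwm.id, pwm.tf_name, pwm.freqs.copy(), pwm.kind, pseudocount=0.0)
    cons = pwm.consensus
    blocks: list[list[int]] = []
    i = 0
    while i < L:
        if i + 1 < L and cons[i] == "C" and cons[i + 1] == "G":
            blocks.append([i, i + 1])
            i += 2
        else:
            blocks.append([i])
            i += 1
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    cols = [j for b in order for j in blocks[b]]
    return Pwm(pwm.id, pwm.tf_name, pwm.freqs[cols].copy(), pwm.kind, pseudocount=0.0)


# ---------------------------------------------------------------------------
# Motif library I/O: MEME minimal format and a flat TSV
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["id", "tf", "position", "A", "C", "G", "T"]


def write_pwm_tsv(pwms: Iterable[Pwm], path: str | Path) -> None:
    """Write motifs as a flat TSV: one row per motif position."""
    rows = []
    for pwm in pwms:
        for pos in range(len(pwm)):
            a, c, g, t = pwm.freqs[pos]
            rows.append((pwm.id, pwm.tf_name, pos, a, c, g, t))
    pd.DataFrame(rows, columns=_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_pwm_tsv(path: str | Path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Read motifs from the flat TSV written by :func:`write_pwm_tsv`."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "tf": str})
    pwms = []
    for motif_id, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("position")
        if not (grp["position"].to_numpy() == np.arange(len(grp))).all():
            raise ValueError(f"motif {motif_id!r}: positions not contiguous from 0")
        pwms.append(
            Pwm(
                id=str(motif_id),
                tf_name=str(grp["tf"].iloc[0]),
                freqs=grp[["A", "C", "G", "T"]].to_numpy(float),
                pseudocount=pseudocount,
            )
        )
    return pwms


def write_meme(pwms: Iterable[Pwm], path: str | Path) -> None:
    """Write motifs in MEME minimal format (letter-probability matrices)."""
    buf = io.StringIO()
    buf.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
    buf.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
    for pwm in pwms:
        buf.write(f"MOTIF {pwm.id} {pwm.tf_name}\n")
        buf.write(f"letter-probability matrix: alength= 4 w= {len(pwm)}\n")
        for row in pwm.freqs:
            buf.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
        buf.write("\n")
    Path(path).write_text(buf.getvalue())


def read_meme(path: str | Path, pseudocount: float = 1e-3) -> list[Pwm]:
    """Read MEME minimal format motifs (letter-probability matrices only)."""
    pwms: list[Pwm] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            motif_id = parts[1]
            tf_name = parts[2] if len(parts) > 2 else parts[1]
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i >= len(lines):
                raise ValueError(f"motif {motif_id!r}: missing probability matrix")
            i += 1
            rows = []
            while i < len(lines):
                fields = lines[i].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"motif {motif_id!r}: empty probability matrix")
            pwms.append(
                Pwm(id=motif_id, tf_name=tf_name, freqs=np.array(rows), pseudocount=pseudocount)
            )
        else:
            i += 1
    return pwms
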