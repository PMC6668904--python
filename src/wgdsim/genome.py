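"""Digit-string genomes, the gene grammar, and the mutation operators.

A genome is a string over the four-digit alphabet {0, 1, 2, 3}, one digit
per nucleotide, stored as a ``numpy.uint8`` array.  Genes are not
pre-specified: they are discovered by scanning the random string with a
fixed grammar.  Every gene consists of a promoter (a TATA box ``1010``
followed by 5-50 four-digit cis-elements) and a coding region (a reserved
four-digit kind word followed by a kind-specific payload).  No interspersed
digits are allowed between components.

Two mutation operators act on genomes: per-digit substitution and
whole-genome duplication (concatenation of the genome with itself).
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

ALPHABET_SIZE = 4

#: The promoter start word.  The polymerase product binds it.
TATA = "1010"

MIN_CIS = 5
MAX_CIS = 50
MIN_SIGNAL_ELEMENTS = 3
MAX_SIGNAL_ELEMENTS = 20
N_IDENTITIES = 1000


class GeneKind(enum.Enum):
    """Resolved gene kinds.

    Structural genes come in promoting (+) / repressing (-) pairs per
    actuator.  Only replication and movement have behavioral effects;
    attack, defense and search are parsed but inert.  Regulatory genes
    encode transcription factors and resolve to activator or repressor.
    """

    STRUCT_REPL_PLUS = "struct_repl_plus"
    STRUCT_REPL_MINUS = "struct_repl_minus"
    STRUCT_MOVE_PLUS = "struct_move_plus"
    STRUCT_MOVE_MINUS = "struct_move_minus"
    REGULATORY_ACTIVATOR = "regulatory_activator"
    REGULATORY_REPRESSOR = "regulatory_repressor"
    POLYMERASE = "polymerase"
    SIGNALING = "signaling"
    STRUCT_ATTACK_PLUS = "struct_attack_plus"
    STRUCT_ATTACK_MINUS = "struct_attack_minus"
    STRUCT_DEFENSE_PLUS = "struct_defense_plus"
    STRUCT_DEFENSE_MINUS = "struct_defense_minus"
    STRUCT_SEARCH_PLUS = "struct_search_plus"
    STRUCT_SEARCH_MINUS = "struct_search_minus"


STRUCTURAL_KINDS = frozenset(k for k in GeneKind if k.value.startswith("struct_"))
REGULATORY_KINDS = frozenset(
    {GeneKind.REGULATORY_ACTIVATOR, GeneKind.REGULATORY_REPRESSOR}
)

# Raw kind words.  "REGULATORY" is generic: the activator/repressor class is
# resolved from the parity of the sign digit that follows the target cis
# word in the payload (even -> activator, odd -> repressor), which yields
# the expected 50/50 split of the two classes on random genomes.
DEFAULT_KIND_WORDS: dict[str, str] = {
    "0001": "STRUCT_REPL_PLUS",
    "0002": "STRUCT_REPL_MINUS",
    "0003": "STRUCT_MOVE_PLUS",
    "0010": "STRUCT_MOVE_MINUS",
    "0011": "REGULATORY",
    "0012": "POLYMERASE",
    "0013": "SIGNALING",
    "0020": "STRUCT_ATTACK_PLUS",
    "0021": "STRUCT_ATTACK_MINUS",
    "0022": "STRUCT_DEFENSE_PLUS",
    "0023": "STRUCT_DEFENSE_MINUS",
    "0030": "STRUCT_SEARCH_PLUS",
    "0031": "STRUCT_SEARCH_MINUS",
}


def word_value(word: str) -> int:
    """Base-4 integer value (0-255) of a 4-digit word."""
    if len(word) != 4 or any(c not in "0123" for c in word):
        raise ValueError(f"not a 4-digit word over 0-3: {word!r}")
    return int(word, 4)


def word_string(value: int) -> str:
    """Inverse of :func:`word_value`."""
    digits = []
    for _ in range(4):
        digits.append(str(value % 4))
        value //= 4
    return "".join(reversed(digits))


TATA_VALUE = word_value(TATA)


@dataclass(frozen=True)
class SignalingEquation:
    """A linear equation over sensor inputs.

    Each element occupies a fixed 8-digit slot: 4 digits of sensor address
    (base-4, reduced modulo the number of sensors at evaluation time) and 4
    digits of weight (base-4 value 0-255 mapped to the signed range
    -128..127).  Elements may address the same sensor repeatedly.
    """

    elements: tuple[tuple[int, int], ...]  # (raw address, signed weight)

    def __post_init__(self) -> None:
        n = len(self.elements)
        if not MIN_SIGNAL_ELEMENTS <= n <= MAX_SIGNAL_ELEMENTS:
            raise ValueError(f"signaling equation must have 3-20 elements, got {n}")


@dataclass(frozen=True)
class Gene:
    """A parsed gene. ``span`` is 0-based half-open into the genome."""

    start: int
    end: int
    kind: GeneKind
    cis_words: tuple[int, ...]  # word values, 0-255
    identity: int  # 0-999
    sign: int  # +1 / -1 for regulatory and structural kinds, 0 otherwise
    target_cis: int | None = None  # regulatory: bound cis word value
    motif: int | None = None  # polymerase: bound motif word value
    equation: SignalingEquation | None = None  # signaling only

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def as_genome(digits: Iterable[int] | str | np.ndarray) -> np.ndarray:
    """Coerce digits (array, list, or string like ``"10102..."``) to a genome."""
    if isinstance(digits, str):
        if digits and not re.fullmatch(r"[0-3]+", digits):
            raise ValueError("genome strings may only contain digits 0-3")
        arr = np.frombuffer(digits.encode("ascii"), dtype=np.uint8) - ord("0")
        return arr.astype(np.uint8)
    arr = np.asarray(digits, dtype=np.uint8)
    if arr.ndim != 1:
        raise ValueError("genome must be one-dimensional")
    if arr.size and arr.max() > 3:
        raise ValueError("genome digits must be in {0,1,2,3}")
    return arr


def genome_to_str(genome: np.ndarray) -> str:
    return "".join(chr(d + ord("0")) for d in genome.tolist())


def random_genome(length: int, rng: np.random.Generator) -> np.ndarray:
    """A uniform random digit string of the given length."""
    if length <= 0:
        raise ValueError(f"genome length must be positive, got {length}")
    return rng.integers(0, ALPHABET_SIZE, size=length, dtype=np.uint8)


class GenomeGenerationError(RuntimeError):
    """Raised when no viable genome is found within the retry budget."""


#: Viability requirement used for simulation founders: the genome must be
#: able to express (polymerase), sense (signaling), replicate and move.
DEFAULT_FOUNDER_KINDS = frozenset(
    {
        GeneKind.POLYMERASE,
        GeneKind.SIGNALING,
        GeneKind.STRUCT_REPL_PLUS,
        GeneKind.STRUCT_MOVE_PLUS,
    }
)


def random_viable_genome(
    length: int,
    rng: np.random.Generator,
    requirements: frozenset[GeneKind] | set[GeneKind] | None = None,
    min_regulatory: int = 12,
    max_tries: int = 500,
    kind_words: dict[str, str] | None = None,
) -> np.ndarray:
    """Draw random genomes until one satisfies the viability requirements.

    ``requirements`` is a set of gene kinds of which at least one copy must
    parse; ``min_regulatory`` additionally requires that many regulatory
    genes (activators or repressors).  ``None`` means the default founder
    requirement; pass an empty set and ``min_regulatory=0`` for a plain
    random genome.
    """
    if requirements is None:
        requirements = DEFAULT_FOUNDER_KINDS
    requirements = frozenset(requirements)
    if not requirements <= frozenset(GeneKind):
        raise ValueError("requirements must be a subset of GeneKind")
    if not requirements and min_regulatory <= 0:
        return random_genome(length, rng)
    last_missing: list[str] = []
    for _ in range(max_tries):
        g = random_genome(length, rng)
        genes = scan_genes(g, kind_words)
        kinds = {gene.kind for gene in genes}
        n_reg = sum(1 for gene in genes if gene.kind in REGULATORY_KINDS)
        missing = [k.value for k in sorted(requirements - kinds, key=lambda k: k.value)]
        if n_reg < min_regulatory:
            missing.append(f"regulatory>={min_regulatory} (found {n_reg})")
        if not missing:
            return g
        last_missing = missing
    raise GenomeGenerationError(
        f"no viable genome of length {length} after {max_tries} tries; "
        f"last draw was missing: {', '.join(last_missing)}"
    )


def identity_of(payload: np.ndarray | Sequence[int] | str) -> int:
    """Product identity (0-999) of a coding payload.

    The first five payload digits are read as a base-4 number (0-1023) and
    reduced modulo 1000.
    """
    window = as_genome(payload)
    if window.size < 5:
        raise ValueError("identity window needs at least 5 digits")
    value = 0
    for d in window[:5].tolist():
        value = value * 4 + d
    return value % N_IDENTITIES


def _word_array(g: np.ndarray) -> np.ndarray:
    """value of the 4-digit word starting at each position (length |g|-3)."""
    if g.size < 4:
        return np.empty(0, dtype=np.int16)
    w = g.astype(np.int16)
    return ((w[:-3] * 4 + w[1:-2]) * 4 + w[2:-1]) * 4 + w[3:]


def _kind_value_table(kind_words: dict[str, str] | None) -> dict[int, str]:
    table = DEFAULT_KIND_WORDS if kind_words is None else kind_words
    values = {}
    for word, name in table.items():
        v = word_value(word)
        if v == TATA_VALUE:
            raise ValueError("the TATA word cannot be a kind word")
        values[v] = name
    return values


def _base4(g: Sequence[int], start: int, n: int) -> int:
    value = 0
    for d in g[start : start + n]:
        value = value * 4 + d
    return value


def _try_parse(
    g: list[int], W: np.ndarray, tata: int, kind_values: dict[int, str]
) -> Gene | None:
    L = len(g)
    # cis block: 4-aligned words after the TATA box, terminated by the first
    # reserved kind word.  An embedded TATA word or a block outside 5-50
    # words aborts the parse.
    p = tata + 4
    n_cis = 0
    cis: list[int] = []
    kind_name: str | None = None
    while True:
        if p + 4 > L:
            return None
        w = int(W[p])
        if w in kind_values:
            kind_name = kind_values[w]
            break
        if w == TATA_VALUE:
            return None
        cis.append(w)
        n_cis += 1
        if n_cis > MAX_CIS:
            return None
        p += 4
    if n_cis < MIN_CIS:
        return None
    q = p + 4  # payload start

    if kind_name == "SIGNALING":
        if q + 2 > L:
            return None
        n_elem = min(MIN_SIGNAL_ELEMENTS + _base4(g, q, 2), MAX_SIGNAL_ELEMENTS)
        end = q + 2 + 8 * n_elem
        if end > L:
            return None
        elements = tuple(
            (_base4(g, a, 4), _base4(g, a + 4, 4) - 128)
            for a in range(q + 2, end, 8)
        )
        return Gene(
            start=tata,
            end=end,
            kind=GeneKind.SIGNALING,
            cis_words=tuple(cis),
            identity=_base4(g, q, 5) % N_IDENTITIES,
            sign=0,
            equation=SignalingEquation(elements),
        )

    # All other kinds carry a fixed 5-digit payload.
    if q + 5 > L:
        return None
    identity = _base4(g, q, 5) % N_IDENTITIES
    end = q + 5
    if kind_name == "REGULATORY":
        sign_digit = int(g[q + 4])
        kind = (
            GeneKind.REGULATORY_ACTIVATOR
            if sign_digit % 2 == 0
            else GeneKind.REGULATORY_REPRESSOR
        )
        return Gene(
            start=tata,
            end=end,
            kind=kind,
            cis_words=tuple(cis),
            identity=identity,
            sign=1 if kind is GeneKind.REGULATORY_ACTIVATOR else -1,
            target_cis=int(W[q]),
        )
    if kind_name == "POLYMERASE":
        return Gene(
            start=tata,
            end=end,
            kind=GeneKind.POLYMERASE,
            cis_words=tuple(cis),
            identity=identity,
            sign=0,
            motif=int(W[q]),
        )
    kind = GeneKind[kind_name]
    sign = 1 if kind.value.endswith("_plus") else -1
    return Gene(
        start=tata,
        end=end,
        kind=kind,
        cis_words=tuple(cis),
        identity=identity,
        sign=sign,
    )


def scan_genes(
    genome: np.ndarray | str, kind_words: dict[str, str] | None = None
) -> list[Gene]:
    """Left-to-right, non-overlapping gene scan.

    At each occurrence of the TATA word a full parse is attempted; on
    success scanning resumes after the gene's end, on failure one digit
    after the TATA occurrence.  Unparseable regions are skipped silently.
    """
    g = as_genome(genome)
    kind_values = _kind_value_table(kind_words)
    W = _word_array(g)
    glist = g.tolist()
    genes: list[Gene] = []
    pos = 0
    for tata in np.flatnonzero(W == TATA_VALUE).tolist():
        if tata < pos:
            continue
        gene = _try_parse(glist, W, tata, kind_values)
        if gene is not None:
            genes.append(gene)
            pos = gene.end
        else:
            pos = tata + 1
    return genes


def apply_substitutions(
    genome: np.ndarray, rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, int]:
    """Mutate each digit independently with the given per-digit probability.

    A substituted digit is replaced by a uniformly chosen *different* digit.
    Returns a mutated copy and the substitution count; the input is left
    untouched.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"substitution rate must be in [0, 1], got {rate}")
    out = genome.copy()
    if rate == 0.0 or genome.size == 0:
        return out, 0
    hits = np.flatnonzero(rng.random(genome.size) < rate)
    if hits.size:
        offsets = rng.integers(1, ALPHABET_SIZE, size=hits.size, dtype=np.uint8)
        out[hits] = (out[hits] + offsets) % ALPHABET_SIZE
    return out, int(hits.size)


def whole_genome_duplicate(genome: np.ndarray) -> np.ndarray:
    """Whole-genome duplication: the genome concatenated with itself."""
    return np.concatenate([genome, genome])


# ---------------------------------------------------------------------------
# FASTA-like genome files: ">id ploidy=N" headers, digit sequence lines.

def write_genomes(
    path, records: Iterable[tuple[str, int, np.ndarray]], width: int = 80
) -> None:
    with open(path, "w") as fh:
        for name, ploidy, genome in records:
            fh.write(f">{name} ploidy={ploidy}\n")
            s = genome_to_str(genome)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def read_genomes(path) -> list[tuple[str, int, np.ndarray]]:
    records: list[tuple[str, int, np.ndarray]] = []
    name: str | None = None
    ploidy = 1
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, ploidy, as_genome("".join(chunks))))
                fields = line[1:].split()
                name = fields[0] if fields else ""
                ploidy = 1
                for f in fields[1:]:
                    if f.startswith("ploidy="):
                        ploidy = int(f.split("=", 1)[1])
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        records.append((name, ploidy, as_genome("".join(chunks))))
    return records
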