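"""Seeded generator of polymer-description corpora for testing and QC drills.

``generate_corpus`` produces labeled records: syntactically/semantically clean
descriptions (``expected == "valid"``), descriptions with an injected syntax
defect (``"syntax"``), or descriptions with an injected semantic defect
labeled by the validation rule it violates (``"V1"``..``"V9"``).  Output is a
pure function of the :class:`CorpusSpec`, including its seed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .alphabet import Alphabet, CrosslinkOntology, packaged_alphabet, packaged_ontology

SEMANTIC_RULES = ("V1", "V2", "V3", "V4", "V5", "V6", "V7", "V8", "V9")

_MODIFIED = {
    "protein": ["{SEP}", "{TPO}", "{PTR}", "{HYP}", "{SEC}"],
    "dna": ["{5mC}", "{6mA}"],
    "rna": ["{9U}", "{74U}"],
}
_CANONICAL = {"protein": "ACDEFGHIKLMNPQRSTVWY", "dna": "ACGT", "rna": "ACGU"}

# inline glycine written out in full; used for inline-definition coverage
_INLINE_GLY = (
    '[id: gly2 | structure: "NCC(O)=O" | l-bond-atom: N1 | l-displaced-atom: H1'
    " | r-bond-atom: C3 | r-displaced-atom: O4 | base-monomer: G]"
)


@dataclass
class CorpusSpec:
    """Parameters of a generated corpus; the seed fixes the output exactly."""

    n_records: int = 100
    alphabet: str = "protein"
    length_range: tuple[int, int] = (5, 30)
    p_modified: float = 0.10
    p_nick: float = 0.10
    p_crosslink: float = 0.30
    p_circular: float = 0.10
    seed: int = 0
    error_mode: str = "none"  # none | syntax | semantic

    def __post_init__(self):
        for name in ("p_modified", "p_nick", "p_crosslink", "p_circular"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.error_mode not in ("none", "syntax", "semantic"):
            raise ValueError(f"unknown error_mode {self.error_mode!r}")
        if self.alphabet not in _CANONICAL:
            raise ValueError(f"unknown alphabet {self.alphabet!r}")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError(f"bad length_range {self.length_range}")


def _random_valid(rng: random.Random, spec: CorpusSpec) -> str:
    """One clean polymer description."""
    lo, hi = spec.length_range
    n = rng.randint(max(lo, 4), max(hi, 4))
    canonical = _CANONICAL[spec.alphabet]
    codes = [rng.choice(canonical) for _ in range(n)]
    for i in range(n):
        if rng.random() < spec.p_modified:
            codes[i] = rng.choice(_MODIFIED[spec.alphabet])
    if spec.alphabet == "protein" and rng.random() < spec.p_modified:
        codes[rng.randrange(n)] = _INLINE_GLY

    circular = rng.random() < spec.p_circular
    attrs = []
    if circular:
        attrs.append("circular")

    xlink_positions: set[int] = set()
    if spec.alphabet == "protein" and rng.random() < spec.p_crosslink and n >= 4:
        i, j = sorted(rng.sample(range(1, n + 1), 2))
        if j - i >= 2:
            codes[i - 1] = "C"
            codes[j - 1] = "C"
            attrs.append(f"x-link: [type: disulfide | l: {i} | r: {j}]")
            xlink_positions = {i, j}

    nick_after = None
    if rng.random() < spec.p_nick and n >= 2:
        nick_after = rng.randint(1, n - 1)

    if not circular and spec.alphabet == "protein" and rng.random() < 0.15:
        codes.insert(0, "{AC}")
        if nick_after is not None:
            nick_after += 1
        attrs = [a if "x-link" not in a else _shift_xlink(a, 1) for a in attrs]

    if rng.random() < 0.10:
        attrs.append(f"extra: [mass: {rng.randint(1, 200)}.{rng.randint(0, 99):02d} | "
                     f"charge: {rng.randint(-3, 3)}]")
    if rng.random() < 0.10:
        attrs.append('comments: "generated record"')

    parts = []
    for k, code in enumerate(codes, start=1):
        parts.append(code)
        if nick_after is not None and k == nick_after:
            parts.append(":")
    text = "".join(parts)
    for attr in attrs:
        text += " | " + attr
    return text


def _shift_xlink(attr: str, delta: int) -> str:
    import re

    def bump(m):
        return f"{m.group(1)} {int(m.group(2)) + delta}"

    return re.sub(r"([lr]:)\s*(\d+)", bump, attr)


def _with_syntax_defect(rng: random.Random, text: str) -> str:
    choice = rng.randrange(5)
    if choice == 0:
        return text + " | x-link: [type: disulfide | l: 1"  # unclosed bracket
    if choice == 1:
        return text[: len(text) // 2] + "!" + text[len(text) // 2 :]
    if choice == 2:
        return "{" + text  # unclosed brace code
    if choice == 3:
        return text + ' | comments: "unterminated'
    return text + " | bogus-attribute: 1"


def _with_semantic_defect(rng: random.Random, spec: CorpusSpec, rule: str) -> str:
    """A protein polymer violating exactly the intended rule (it may also trip
    a neighboring rule; validation must at least report the intended one)."""
    n = rng.randint(6, 12)
    codes = [rng.choice(_CANONICAL["protein"]) for _ in range(n)]
    attrs: list[str] = []
    if rule == "V1":
        # interior residue with no left bond atoms (an inline left cap)
        codes[rng.randint(2, n - 1) - 1] = (
            '[id: badcap | structure: "CC(O)=O" | r-bond-atom: C2 | r-displaced-atom: O3]'
        )
    elif rule == "V2":
        codes[rng.randint(2, n - 1) - 1] = "{AC}"  # left cap misplaced
    elif rule == "V3":
        codes[-1] = "{NH2}"  # right cap blocks ring closure
        attrs.append("circular")
    elif rule == "V4":
        codes[rng.randrange(n)] = (
            '[id: bad | structure: "NCC(O)=O" | l-bond-atom: S1 | '
            "r-bond-atom: C3 | r-displaced-atom: O4]"
        )
    elif rule == "V5":
        codes[rng.randint(2, n) - 1] = (
            '[id: badh | structure: "NCC(O)=O" | l-bond-atom: N1 | '
            "l-displaced-atom: H3 | r-bond-atom: C3 | r-displaced-atom: O4]"
        )
    elif rule == "V6":
        codes[0] = "C"
        attrs.append(f"x-link: [type: disulfide | l: 1 | r: {n + rng.randint(1, 9)}]")
    elif rule == "V7":
        i, j = 2, n - 1
        codes[i - 1] = "A"
        codes[j - 1] = "C"
        attrs.append(f"x-link: [type: disulfide | l: {i} | r: {j}]")
    elif rule == "V8":
        i, j, k = 1, 3, 5
        codes[i - 1] = codes[j - 1] = codes[k - 1] = "C"
        attrs.append(f"x-link: [type: disulfide | l: {i} | r: {j}]")
        attrs.append(f"x-link: [type: disulfide | l: {i} | r: {k}]")
    elif rule == "V9":
        codes[2] = (
            '[id: uncertain | structure: "NC(C(O)=O)CO" | l-bond-atom: N1 | '
            "l-displaced-atom: H1 | r-bond-atom: C3 | r-displaced-atom: O4 | "
            f"base-monomer: S | position: 3-{n + 5}]"
        )
    else:
        raise ValueError(f"unknown rule {rule!r}")
    text = "".join(codes)
    for attr in attrs:
        text += " | " + attr
    return text


def generate_corpus(spec: CorpusSpec) -> list[tuple[str, str]]:
    """Generate ``spec.n_records`` labeled (description, expected) records."""
    rng = random.Random(spec.seed)
    records: list[tuple[str, str]] = []
    for k in range(spec.n_records):
        if spec.error_mode == "none":
            records.append((_random_valid(rng, spec), "valid"))
        elif spec.error_mode == "syntax":
            base = _random_valid(rng, spec)
            records.append((_with_syntax_defect(rng, base), "syntax"))
        else:
            rule = SEMANTIC_RULES[k % len(SEMANTIC_RULES)]
            records.append((_with_semantic_defect(rng, spec, rule), rule))
    return records


def generate_complex_corpus(n_records: int, seed: int) -> list[tuple[str, dict[str, str]]]:
    """Random complex descriptions paired with subunit polymer strings.

    Every record is semantically clean: crosslink slots point at cysteines
    planted at residue 1 of each subunit, so disulfides always resolve.
    """
    rng = random.Random(seed)
    records = []
    for _ in range(n_records):
        n_subunits = rng.randint(1, 3)
        subunits: dict[str, str] = {}
        terms = []
        slots = []
        for s in range(n_subunits):
            sid = f"su{s + 1}"
            stoich = rng.randint(1, 4)
            seq = "C" + "".join(
                rng.choice(_CANONICAL["protein"]) for _ in range(rng.randint(3, 11))
            )
            subunits[sid] = seq
            terms.append(f"{stoich} * {sid}")
            slots.extend((sid, copy) for copy in range(1, stoich + 1))
        text = " + ".join(terms)
        if len(slots) >= 2 and rng.random() < 0.6:
            (s1, c1), (s2, c2) = rng.sample(slots, 2)
            text += f" | x-link: [type: disulfide | l: {s1}({c1})-1 | r: {s2}({c2})-1]"
        records.append((text, subunits))
    return records


def corpus_alphabet(spec: CorpusSpec) -> Alphabet:
    if spec.error_mode == "semantic":
        return packaged_alphabet("protein")
    return packaged_alphabet(spec.alphabet)


def corpus_ontology() -> CrosslinkOntology:
    return packaged_ontology()
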