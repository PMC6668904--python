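"""Independent naive gene scanner used as a test oracle.

Deliberately string-based and simple-minded: it re-implements the gene
grammar (TATA box, 5-50 cis words, kind word, kind-specific payload)
directly from its written description, sharing no code with the package.
"""

from __future__ import annotations

TATA = "1010"

KIND_WORDS = {
    "0001": "struct_repl_plus",
    "0002": "struct_repl_minus",
    "0003": "struct_move_plus",
    "0010": "struct_move_minus",
    "0011": "regulatory",
    "0012": "polymerase",
    "0013": "signaling",
    "0020": "struct_attack_plus",
    "0021": "struct_attack_minus",
    "0022": "struct_defense_plus",
    "0023": "struct_defense_minus",
    "0030": "struct_search_plus",
    "0031": "struct_search_minus",
}


def _identity(payload: str) -> int:
    return int(payload[:5], 4) % 1000


def _parse_at(s: str, t: int):
    """Try to parse a gene whose TATA box starts at position t."""
    p = t + 4
    cis = []
    kind = None
    while True:
        word = s[p : p + 4]
        if len(word) < 4:
            return None
        if word in KIND_WORDS:
            kind = KIND_WORDS[word]
            break
        if word == TATA:
            return None
        cis.append(word)
        if len(cis) > 50:
            return None
        p += 4
    if len(cis) < 5:
        return None
    q = p + 4
    if kind == "signaling":
        if len(s) < q + 2:
            return None
        n_elem = min(3 + int(s[q : q + 2], 4), 20)
        end = q + 2 + 8 * n_elem
        if end > len(s):
            return None
        elements = [
            (int(s[a : a + 4], 4), int(s[a + 4 : a + 8], 4) - 128)
            for a in range(q + 2, end, 8)
        ]
        return dict(
            start=t, end=end, kind=kind, cis=cis,
            identity=_identity(s[q:]), elements=elements,
        )
    if len(s) < q + 5:
        return None
    payload = s[q : q + 5]
    out = dict(start=t, end=q + 5, kind=kind, cis=cis, identity=_identity(payload))
    if kind == "regulatory":
        out["target"] = payload[:4]
        out["kind"] = (
            "regulatory_activator" if int(payload[4]) % 2 == 0
            else "regulatory_repressor"
        )
        out["sign"] = 1 if out["kind"] == "regulatory_activator" else -1
    return out


def oracle_scan(s: str) -> list[dict]:
    """Left-to-right non-overlapping scan; resume +1 after a failed TATA."""
    genes = []
    pos = 0
    while True:
        t = s.find(TATA, pos)
        if t == -1:
            return genes
        g = _parse_at(s, t)
        if g is None:
            pos = t + 1
        else:
            genes.append(g)
            pos = g["end"]
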