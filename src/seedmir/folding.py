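"""Thin wrapper around the ViennaRNA MFE folder plus dot-bracket helpers."""

from __future__ import annotations

import RNA

from ._seq import check_nucleotides, to_rna


def fold(sequence: str) -> tuple[str, float]:
    """Predict the MFE secondary structure of a sequence.

    Returns (dot_bracket, MFE in kcal/mol). T is read as U; N and other
    symbols are rejected. Pseudoknot-free by construction of the engine.
    """
    check_nucleotides(sequence, allow_n=False)
    structure, mfe = RNA.fold(to_rna(sequence))
    return structure, float(mfe)


def pair_table(dot_bracket: str) -> list[int]:
    """0-based partner index per position, -1 for unpaired."""
    pt = [-1] * len(dot_bracket)
    stack: list[int] = []
    for i, ch in enumerate(dot_bracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket string")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket string")
    return pt


def hairpin_loops(dot_bracket: str) -> list[tuple[int, int, int]]:
    """Hairpin loops as (start, end, depth): the unpaired run [start, end)
    closed by an innermost pair, with its nesting depth."""
    pt = pair_table(dot_bracket)
    loops = []
    depth = 0
    i = 0
    n = len(dot_bracket)
    while i < n:
        ch = dot_bracket[i]
        if ch == "(":
            depth += 1
            j = pt[i]
            # innermost iff no pairs strictly inside (i, j)
            if all(pt[k] == -1 for k in range(i + 1, j)):
                loops.append((i + 1, j, depth))
                i = j
                depth -= 1
                continue
        elif ch == ")":
            depth -= 1
        i += 1
    return loops


def terminal_loop(dot_bracket: str) -> tuple[int, int] | None:
    """The most deeply nested hairpin loop (ties: first), or None."""
    loops = hairpin_loops(dot_bracket)
    if not loops:
        return None
    start, end, _ = max(loops, key=lambda t: (t[2], -(t[1] - t[0])))
    return start, end
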