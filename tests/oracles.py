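"""Brute-force reference implementations used only to cross-check the
package's optimized code paths.

Each oracle is written for transparency, not speed: full matrices,
explicit candidate lists, per-base expansion, O(N*M) scans.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_adapter_identity(
    read_seq: str,
    barcode: str,
    match: int = 3,
    mismatch: int = -6,
    gap_open: int = -5,
    gap_extend: int = -2,
):
    """Exhaustive three-state DP over the full read (no window cap),
    with explicit traceback pointers; matches and inserted columns are
    recovered by walking the traceback rather than propagated forward.

    Optimum: maximise score, then leftmost start, then smallest end;
    predecessor ties resolve substitution > gap-in-read > gap-in-barcode
    > fresh start.  Returns (identity_pct, start, end).
    """
    read = read_seq.upper()
    bc = barcode.upper()
    n, m = len(read), len(bc)
    # value[(i, j, state)] = (score, start); ptr -> (i, j, state) or "origin"
    value: dict[tuple[int, int, str], tuple[float, int]] = {}
    ptr: dict[tuple[int, int, str], object] = {}

    def better(a: tuple[float, int], b: tuple[float, int]) -> bool:
        # strictly better: higher score, or equal score and smaller start
        return a[0] > b[0] or (a[0] == b[0] and a[1] < b[1])

    for j in range(1, m + 1):
        if j == 1:
            value[(0, j, "X")] = (gap_open, 0)
            ptr[(0, j, "X")] = "origin"
        else:
            prev = value[(0, j - 1, "X")]
            value[(0, j, "X")] = (prev[0] + gap_extend, prev[1])
            ptr[(0, j, "X")] = (0, j - 1, "X")

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            # M state: substitution consuming read[i-1], barcode[j-1]
            sub = (
                match
                if read[i - 1] == bc[j - 1] and read[i - 1] != "N"
                else mismatch
            )
            candidates = []
            for state in ("M", "X", "Y"):
                key = (i - 1, j - 1, state)
                if key in value:
                    candidates.append((value[key], key))
            if j == 1:
                candidates.append(((0.0, i - 1), "origin"))
            if candidates:
                chosen_val, chosen_ptr = candidates[0]
                for val, p in candidates[1:]:
                    if better(val, chosen_val):
                        chosen_val, chosen_ptr = val, p
                value[(i, j, "M")] = (chosen_val[0] + sub, chosen_val[1])
                ptr[(i, j, "M")] = chosen_ptr
            # X state: gap in read (consumes barcode only); gap-open
            # sources (M, Y, origin) outrank gap-extension on ties
            candidates = []
            for state, cost in (("M", gap_open), ("Y", gap_open)):
                key = (i, j - 1, state)
                if key in value:
                    candidates.append(((value[key][0] + cost, value[key][1]), key))
            if j == 1:
                candidates.append(((gap_open, i), "origin"))
            key = (i, j - 1, "X")
            if key in value:
                candidates.append(((value[key][0] + gap_extend, value[key][1]), key))
            if candidates:
                chosen_val, chosen_ptr = candidates[0]
                for val, p in candidates[1:]:
                    if better(val, chosen_val):
                        chosen_val, chosen_ptr = val, p
                value[(i, j, "X")] = chosen_val
                ptr[(i, j, "X")] = chosen_ptr
            # Y state: gap in barcode (consumes read only)
            candidates = []
            for state, cost in (("M", gap_open), ("X", gap_open), ("Y", gap_extend)):
                key = (i - 1, j, state)
                if key in value:
                    candidates.append(((value[key][0] + cost, value[key][1]), key))
            if candidates:
                chosen_val, chosen_ptr = candidates[0]
                for val, p in candidates[1:]:
                    if better(val, chosen_val):
                        chosen_val, chosen_ptr = val, p
                value[(i, j, "Y")] = chosen_val
                ptr[(i, j, "Y")] = chosen_ptr

    best_key = None
    best_val = (NEG, 0)
    for i in range(0, n + 1):
        for state in ("M", "X", "Y"):
            key = (i, m, state)
            if key in value and better(value[key], best_val):
                best_val, best_key = value[key], key

    # walk the traceback, counting matched and inserted columns
    matches = inserted = 0
    key = best_key
    while key != "origin":
        i, j, state = key
        if state == "M" and read[i - 1] == bc[j - 1] and read[i - 1] != "N":
            matches += 1
        elif state == "Y":
            inserted += 1
        key = ptr[key]
    identity = 100.0 * matches / (m + inserted)
    return identity, best_val[1], best_key[0]


def oracle_five_prime_clip(cigar: str, strand: str) -> int:
    """Expand the CIGAR to one character per base and count the clipped
    prefix at the strand-appropriate end."""
    expanded = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            expanded.extend(ch * int(num))
            num = ""
    if strand == "-":
        expanded = expanded[::-1]
    clip = 0
    for op in expanded:
        if op in "SH":
            clip += 1
        else:
            break
    return clip


def oracle_closest_tss(chrom, strand, five_prime_pos, transcripts):
    """O(N) scan over all transcripts for the nearest same-strand TSS;
    ties prefer the smaller TSS position, then transcript_id."""
    best = None
    for t in sorted(transcripts, key=lambda t: (t.tss_pos, t.transcript_id)):
        if t.chrom != chrom or t.strand != strand:
            continue
        d = (
            five_prime_pos - t.tss_pos
            if t.strand == "+"
            else t.tss_pos - five_prime_pos
        )
        if best is None or abs(d) < abs(best[0]):
            best = (d, t)
    return best


def oracle_single_linkage(positions, gap):
    """Repeated pairwise merging until fixpoint."""
    groups = [[p] for p in sorted(positions)]
    changed = True
    while changed:
        changed = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                if any(
                    abs(x - y) <= gap for x in groups[a] for y in groups[b]
                ):
                    groups[a] += groups[b]
                    del groups[b]
                    changed = True
                    break
            if changed:
                break
    return sorted(sorted(g) for g in groups)
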