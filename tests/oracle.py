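"""Independent brute-force event enumerator used to cross-check the detector.

Works directly on plain chain data (strand + exon tuples) with pairwise
scans and explicit dictionaries -- no splice graph, no shared code with the
package beyond the rule statements themselves: retained-intron and
skipped-exon combinations are counted as distinct supported patterns per
cluster of co-observed features; alternative sites are counted against the
prevalent site (plurality, ties to the longest intron, then leftmost); a
deviant donor exclusively paired with a deviant acceptor is one joint event.
"""

from __future__ import annotations

from itertools import combinations


def _introns(exons):
    return [(exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)]


def _contains(exon, iv):
    return exon[0] <= iv[0] and iv[1] <= exon[1]


def _merge_groups(items, pairs):
    """Partition items into connected components given linked pairs."""
    groups = [{x} for x in items]
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            ga = next(g for g in groups if a in g)
            gb = next(g for g in groups if b in g)
            if ga is not gb:
                ga |= gb
                groups.remove(gb)
                changed = True
    return [tuple(sorted(g)) for g in groups]


def _pattern_count(members, status_of):
    """Distinct supported on/off combinations (>=1 'on') per cluster."""
    linked = [
        (a, b)
        for a, b in combinations(members, 2)
        if any(status_of(t, a) and status_of(t, b) for t in status_of.transcripts)
    ]
    total = 0
    for cluster in _merge_groups(members, linked):
        patterns = set()
        for t in status_of.transcripts:
            st = [status_of(t, m) for m in cluster]
            if all(st):
                vec = tuple(1 if s == "on" else 0 for s in st)
                if any(vec):
                    patterns.add(vec)
            else:
                for i, s in enumerate(st):
                    if s == "on":
                        patterns.add(tuple(1 if j == i else 0 for j in range(len(cluster))))
        total += len(patterns)
    return total


class _Status:
    def __init__(self, transcripts, fn):
        self.transcripts = transcripts
        self._fn = fn

    def __call__(self, t, m):
        return self._fn(t, m)


def oracle_counts(chains):
    """(IR, SE, Alt3, Alt5, AltB) for a list of ExonChain-like objects."""
    strand = chains[0].strand
    exons_of = {c.transcript_id: list(c.exons) for c in chains}
    tids = sorted(exons_of)
    introns_of = {t: _introns(exons_of[t]) for t in tids}
    all_introns = sorted({iv for t in tids for iv in introns_of[t]})

    # --- intron retention -------------------------------------------------
    def retained_in(t, iv):
        return any(_contains(e, iv) for e in exons_of[t])

    ir_capable = [iv for iv in all_introns if any(retained_in(t, iv) for t in tids)]

    def ir_status(t, iv):
        if retained_in(t, iv):
            return "on"
        if iv in introns_of[t]:
            return "off"
        return None

    n_ir = _pattern_count(ir_capable, _Status(tids, ir_status))

    # --- cassette exons ---------------------------------------------------
    internal = {}  # exon interval -> dict(includers, left donors, right acceptors)
    for t in tids:
        for k in range(1, len(exons_of[t]) - 1):
            e = tuple(exons_of[t][k])
            rec = internal.setdefault(e, {"inc": set(), "ld": set(), "ra": set()})
            rec["inc"].add(t)
            rec["ld"].add(introns_of[t][k - 1][0])
            rec["ra"].add(introns_of[t][k][1])

    def skip_block(iv):
        inside = sorted(e for e in internal if iv[0] <= e[0] and e[1] <= iv[1])
        if inside and iv[0] in internal[inside[0]]["ld"] and iv[1] in internal[inside[-1]]["ra"]:
            return inside
        return []

    skippers = {}
    for t in tids:
        for iv in introns_of[t]:
            for e in skip_block(iv):
                skippers.setdefault(e, set()).add(t)
    se_capable = sorted(skippers)

    def se_status(t, e):
        if list(e) in [list(x) for x in exons_of[t]]:
            return "off"
        if t in skippers.get(e, set()):
            return "on"
        return None

    n_se = _pattern_count(se_capable, _Status(tids, se_status))

    # --- alternative sites ------------------------------------------------
    support = {iv: {t for t in tids if iv in introns_of[t]} for iv in all_introns}
    skip_introns = {iv for iv in all_introns if skip_block(iv)}
    cand = [iv for iv in all_introns if iv not in set(ir_capable) | skip_introns]

    def side_kind(side):  # genomic start = donor on '+', acceptor on '-'
        if side == 0:
            return "Alt5" if strand == "+" else "Alt3"
        return "Alt3" if strand == "+" else "Alt5"

    n_alt = {"Alt5": 0, "Alt3": 0}
    deviant = {0: set(), 1: set()}  # genomic side -> deviant site positions
    for side in (0, 1):
        shared_vals = sorted({iv[side] for iv in cand})
        for b in shared_vals:
            members = [iv for iv in cand if iv[side] == b]
            sites = sorted({iv[1 - side] for iv in members})
            if len(sites) < 2:
                continue
            best = None
            for s in sites:
                n_sup = len({t for iv in members if iv[1 - side] == s for t in support[iv]})
                length = abs(s - b)
                key = (-n_sup, -length, s)
                if best is None or key < best[0]:
                    best = (key, s)
            for s in sites:
                if s != best[1]:
                    n_alt[side_kind(1 - side)] += 1
                    deviant[1 - side].add(s)

    shared0 = {b for b in {iv[0] for iv in cand}
               if sum(1 for iv in cand if iv[0] == b) > 1}
    shared1 = {b for b in {iv[1] for iv in cand}
               if sum(1 for iv in cand if iv[1] == b) > 1}
    for iv in cand:
        if iv[0] in shared0 or iv[1] in shared1:
            continue
        rivals = [o for o in cand if o != iv and o[0] < iv[1] and iv[0] < o[1]]
        if not rivals:
            continue
        best = None
        for o in rivals + [iv]:
            key = (-len(support[o]), -(o[1] - o[0]), o)
            if best is None or key < best[0]:
                best = (key, o)
        if best[1] == iv:
            continue
        n_alt[side_kind(0)] += 1
        n_alt[side_kind(1)] += 1
        deviant[0].add(iv[0])
        deviant[1].add(iv[1])

    # --- joint 3'/5' merge ------------------------------------------------
    donor_side = 0 if strand == "+" else 1
    n_altb = 0
    used_acceptors = set()
    for d in sorted(deviant[donor_side]):
        with_d = [iv for iv in all_introns if iv[donor_side] == d]
        if len(with_d) != 1:
            continue
        a = with_d[0][1 - donor_side]
        if a not in deviant[1 - donor_side] or a in used_acceptors:
            continue
        with_a = [iv for iv in all_introns if iv[1 - donor_side] == a]
        if with_a != with_d:
            continue
        n_altb += 1
        used_acceptors.add(a)
    alt5_kind, alt3_kind = "Alt5", "Alt3"
    return (
        n_ir,
        n_se,
        n_alt[alt3_kind] - n_altb,
        n_alt[alt5_kind] - n_altb,
        n_altb,
    )
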