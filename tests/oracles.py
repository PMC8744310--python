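"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's indexed/vectorized code paths:
coverage is checked base by base, overlaps all-pairs, splice sites by
direct enumeration over reference transcripts, the LOQ by an explicit
breakpoint grid loop, and ORFs by scanning every ATG.
"""

from __future__ import annotations

import numpy as np


def per_base_coverage_pass(segments, exon_start, exon_end, min_depth, min_fraction):
    """Naive per-base scan over an RLE segment list."""
    n_ok = 0
    for pos in range(exon_start, exon_end):
        depth = 0
        for s, e, d in segments:
            if s <= pos < e:
                depth = d
                break
        if depth >= min_depth:
            n_ok += 1
    return n_ok / (exon_end - exon_start) >= min_fraction


def brute_force_orf(seq):
    """Best ATG-initiated ORF by scanning every start position."""
    seq = seq.upper()
    stops = {"TAA", "TAG", "TGA"}
    best = None  # (length, -start) maximized
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq) and seq[j : j + 3] not in stops:
            j += 3
        end = j + 3 if j + 3 <= len(seq) and seq[j : j + 3] in stops else (
            i + ((len(seq) - i) // 3) * 3
        )
        length = end - i
        if best is None or (length, -i) > (best[0], -best[1]):
            best = (length, i, end)
    return best  # (length, start, end) or None


def fickett_oracle(seq):
    """Straight-from-tables TESTCODE computation, looping explicitly."""
    pos_prob = {
        "A": [0.94, 0.68, 0.84, 0.93, 0.58, 0.68, 0.45, 0.34, 0.20, 0.22],
        "C": [0.80, 0.70, 0.70, 0.81, 0.66, 0.48, 0.51, 0.33, 0.30, 0.23],
        "G": [0.90, 0.88, 0.74, 0.64, 0.53, 0.48, 0.27, 0.16, 0.08, 0.08],
        "T": [0.97, 0.97, 0.91, 0.68, 0.69, 0.44, 0.54, 0.20, 0.09, 0.09],
    }
    pos_weight = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
    pos_bins = [1.9, 1.8, 1.7, 1.6, 1.5, 1.4, 1.3, 1.2, 1.1, 0.0]
    con_prob = {
        "A": [0.28, 0.49, 0.44, 0.55, 0.62, 0.49, 0.67, 0.65, 0.81, 0.21],
        "C": [0.82, 0.64, 0.51, 0.64, 0.59, 0.59, 0.43, 0.44, 0.39, 0.31],
        "G": [0.40, 0.54, 0.47, 0.64, 0.64, 0.73, 0.41, 0.41, 0.33, 0.29],
        "T": [0.28, 0.24, 0.39, 0.40, 0.55, 0.75, 0.56, 0.69, 0.51, 0.58],
    }
    con_weight = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}
    con_bins = [0.33, 0.31, 0.29, 0.27, 0.25, 0.23, 0.21, 0.19, 0.17, 0.0]
    seq = seq.upper()
    score = 0.0
    for base in "ACGT":
        counts = [0, 0, 0]
        for i, ch in enumerate(seq):
            if ch == base:
                counts[i % 3] += 1
        posv = max(counts) / (min(counts) + 1)
        conv = seq.count(base) / len(seq)
        pi = next(i for i, b in enumerate(pos_bins) if posv >= b)
        ci = next(i for i, b in enumerate(con_bins) if conv >= b)
        score += pos_prob[base][pi] * pos_weight[base]
        score += con_prob[base][ci] * con_weight[base]
    return score


def bh_oracle(pvals):
    """Closed-form step-up on sorted p-values."""
    import statsmodels.stats.multitest as smm

    return smm.multipletests(pvals, method="fdr_bh")[1]


def loq_grid_oracle(conc, tpm, pseudo=0.01):
    """Exhaustive breakpoint grid search with explicit polyfit loops.

    Returns (breakpoint, total_sse); single-line fit wins ties within 1e-9
    and reports the minimum concentration.
    """
    conc = np.asarray(conc, float)
    x = np.log2(conc)
    y = np.log2(np.asarray(tpm, float) + pseudo)

    def sse_line(xs, ys):
        if len(xs) < 2 or np.ptp(xs) == 0:
            return float(((ys - ys.mean()) ** 2).sum())
        c = np.polyfit(xs, ys, 1)
        return float(((ys - np.polyval(c, xs)) ** 2).sum())

    def sse_left(xs, ys):
        flat = float(((ys - ys.mean()) ** 2).sum())
        return min(flat, sse_line(xs, ys))

    single = sse_line(x, y)
    best_bp, best_sse = None, None
    for c in np.unique(conc)[1:-1]:
        left = conc < c
        if left.sum() < 2 or (~left).sum() < 2:
            continue
        total = sse_left(x[left], y[left]) + sse_line(x[~left], y[~left])
        if best_sse is None or total < best_sse - 1e-15:
            best_bp, best_sse = float(c), total
    if best_sse is None or single <= best_sse + 1e-9:
        return float(np.unique(conc)[0]), single
    return best_bp, best_sse


def overlap_pairs_oracle(windows, peaks):
    """All-pairs half-open interval intersection counts."""
    counts = {}
    for wid, (wchrom, ws, we) in windows.items():
        n = 0
        for pchrom, ps, pe in peaks:
            if pchrom == wchrom and max(ws, ps) < min(we, pe):
                n += 1
        counts[wid] = n
    return counts


def novelty_oracle(candidate, reference_transcripts):
    """Direct enumeration of novelty categories for one candidate.

    ``candidate`` and each reference transcript are dicts with keys chrom,
    strand, exons (list of (start, end)). Returns a dict of counts/flags.
    """
    c = candidate
    same = [
        r
        for r in reference_transcripts
        if r["chrom"] == c["chrom"] and r["strand"] == c["strand"]
    ]
    donors, acceptors, junctions, tss, tts = set(), set(), set(), set(), set()
    ref_exons = []
    for r in same:
        exons = sorted(r["exons"])
        ref_exons.extend(exons)
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if r["strand"] == "+":
                donors.add(e1)
                acceptors.add(s2)
            else:
                donors.add(s2)
                acceptors.add(e1)
            junctions.add((e1, s2))
        if r["strand"] == "+":
            tss.add(exons[0][0])
            tts.add(exons[-1][1] - 1)
        else:
            tss.add(exons[-1][1] - 1)
            tts.add(exons[0][0])

    exons = sorted(c["exons"])
    out = {
        "cassette": 0,
        "donor": 0,
        "acceptor": 0,
        "both": 0,
        "junction": 0,
        "novel_tss": False,
        "novel_tts": False,
    }
    n = len(exons)
    for i, (s, e) in enumerate(exons):
        overlaps = any(max(s, rs) < min(e, re) for rs, re in ref_exons)
        if 0 < i < n - 1 and not overlaps:
            out["cassette"] += 1
            continue
        left_known = s in (acceptors if c["strand"] == "+" else donors)
        right_known = e in (donors if c["strand"] == "+" else acceptors)
        novel_left = i > 0 and not left_known
        novel_right = i < n - 1 and not right_known
        if novel_left and novel_right:
            out["both"] += 1
        elif novel_left:
            out["acceptor" if c["strand"] == "+" else "donor"] += 1
        elif novel_right:
            out["donor" if c["strand"] == "+" else "acceptor"] += 1
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if (e1, s2) in junctions:
            continue
        d = e1 if c["strand"] == "+" else s2
        a = s2 if c["strand"] == "+" else e1
        if d in donors and a in acceptors:
            out["junction"] += 1
    if c["strand"] == "+":
        out["novel_tss"] = exons[0][0] not in tss
        out["novel_tts"] = exons[-1][1] - 1 not in tts
    else:
        out["novel_tss"] = exons[-1][1] - 1 not in tss
        out["novel_tts"] = exons[0][0] not in tts
    return out


def switch_p_oracle(ifm, labels, cond1):
    """Exhaustive permutation p for the sum|dIF| statistic, one gene."""
    from itertools import combinations

    ifm = np.asarray(ifm, float)
    n = ifm.shape[1]
    k = int(sum(1 for l in labels if l == cond1))

    def stat(mask):
        m1 = np.nanmean(ifm[:, mask], axis=1)
        m2 = np.nanmean(ifm[:, [i for i in range(n) if i not in mask]], axis=1)
        d = m1 - m2
        d = np.where(np.isnan(d), 0.0, d)
        return float(np.abs(d).sum())

    obs = stat([i for i, l in enumerate(labels) if l == cond1])
    null = [stat(list(c)) for c in combinations(range(n), k)]
    return sum(1 for s in null if s >= obs - 1e-12) / len(null)
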