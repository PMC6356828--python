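"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own search structures: the assignment
oracle is an exhaustive all-pairs minimum-distance scan.
"""

import numpy as np


def brute_force_assign(peaks, genes, anchor="summit", max_abs_distance=100_000):
    """Exhaustive all-pairs nearest-TSS scan (full peak × gene distance matrix).

    Returns a set of (peak index, gene index, signed distance, ambiguous)
    tuples covering every gene attaining the minimal |distance| per peak.
    """
    out = set()
    gene_chroms = sorted({g.chrom for g in genes})
    for chrom in gene_chroms:
        gidx = [gi for gi, g in enumerate(genes) if g.chrom == chrom]
        pidx = [pi for pi, p in enumerate(peaks) if p.chrom == chrom]
        if not pidx:
            continue
        tss = np.array([genes[gi].tss0 for gi in gidx])
        anchors = np.array([peaks[pi].anchor_point(anchor) for pi in pidx])
        dist = np.abs(anchors[:, None] - tss[None, :])  # all pairs
        best = dist.min(axis=1)
        for row, pi in enumerate(pidx):
            if best[row] > max_abs_distance:
                continue
            winners = np.flatnonzero(dist[row] == best[row])
            for w in winners:
                gi = gidx[int(w)]
                gene = genes[gi]
                a = int(anchors[row])
                signed = a - gene.tss0 if gene.strand == "+" else gene.tss0 - a
                out.add((pi, gi, signed, len(winners) > 1))
    return out


def assignment_key_set(peaks, genes, result):
    """Normalise an AssignmentResult to the oracle's tuple representation."""
    peak_index = {id(p): i for i, p in enumerate(peaks)}
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    return {
        (peak_index[id(a.peak)], gene_index[a.gene.gene_id],
         a.signed_distance, a.ambiguous)
        for a in result.assignments
    }


def random_instance(rng, n_peaks, n_genes, chrom_length=1_000_000, n_chroms=2):
    """Random peaks and genes sharing a chromosome namespace."""
    from hepatarget.annotation_and_peaks import GeneModel, Peak

    genes = []
    for i in range(n_genes):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss0 = int(rng.integers(5000, chrom_length - 5000))
        length = int(rng.integers(500, 3000))
        if strand == "+":
            span = (tss0, tss0 + length)
        else:
            span = (tss0 + 1 - length, tss0 + 1)
        genes.append(GeneModel(f"G{i}", f"G{i}", chrom, strand, span[0], span[1]))
    peaks = []
    for i in range(n_peaks):
        chrom = f"chr{int(rng.integers(1, n_chroms + 1))}"
        start = int(rng.integers(0, chrom_length - 500))
        end = start + int(rng.integers(100, 500))
        summit = int(rng.integers(start, end)) if rng.random() < 0.7 else None
        peaks.append(Peak(chrom, start, end, f"p{i}", 1.0, summit))
    return peaks, genes
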