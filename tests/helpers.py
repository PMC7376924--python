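"""Shared toy-genome construction helpers for the test suite."""

from panclean.annotation_io import GeneRecord, translate
from panclean.clustering import SeqCluster


def make_genomes(layouts, seqs):
    """layouts: {genome: [family, ...]} in gene order; seqs: {family: dna}.
    Returns (records, clusters) with one cluster per family."""
    records = []
    members = {}
    for genome in sorted(layouts):
        pos = 0
        for i, fam in enumerate(layouts[genome]):
            dna = seqs[fam]
            gid = f"{genome}|g{i:03d}"
            records.append(
                GeneRecord(gid, genome, "c1", pos, pos + len(dna), "+", dna,
                           translate(dna), annotation=fam, position_index=i)
            )
            members.setdefault(fam, []).append(gid)
            pos += len(dna) + 50
    by_id = {r.gene_id: r for r in records}
    clusters = [
        SeqCluster(ci, max(mem, key=lambda g: (len(by_id[g].dna_seq), g)), mem, 0.98)
        for ci, (fam, mem) in enumerate(sorted(members.items()))
    ]
    return records, clusters


SEQS = {
    f: ("ATG" + c * 30 + "TAA")
    for f, c in zip("ABCDXY", ("AAACGT", "CCCGTA", "GGGTAC", "TTTACG", "ACGACG", "GTAGTA"))
}
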