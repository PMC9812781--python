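"""Call tandem-repeat expansions at a single locus and filter by rarity.

An expansion is a repeat allele much longer than the rest of the cohort at
the same locus-motif.  One-dimensional DBSCAN labels the dense baseline
lengths as clusters; noise points strictly above every clustered length
are expansion carriers.  An expansion is then *rare* when fewer than 0.1%
of the population panel carries it.
"""

from treburden import (
    CallParams,
    LocusMotifProfile,
    call_expansions,
    canonical_motif,
    classify_cpg,
    dbscan_1d,
    rarity_filter,
)

# motif bookkeeping: rotations and reverse complements name the same repeat
print("canonical_motif('GCA') =", canonical_motif("GCA"))
print("classify_cpg('CCG') =", classify_cpg("CCG"))

# DBSCAN on a length vector: five baseline lengths, one 55 bp outlier
labels = dbscan_1d([10, 11, 10, 12, 11, 55], eps=5, min_samples=3)
print("dbscan labels:", labels.tolist(), "(-1 = noise)")

# the same vector as a cohort profile -> a TRE call with its carrier
profile = LocusMotifProfile(
    contig="chr1",
    start=100,
    end=160,
    motif="AGC",
    lengths={"s1": 10, "s2": 11, "s3": 10, "s4": 12, "s5": 11, "s6": 55},
)
tre = call_expansions(profile, CallParams(eps=5, min_samples=3, min_cohort=5))
print("carriers:", sorted(tre.carriers))

# rarity against a 2504-sample panel: 2 carriers ~ 0.08% < 0.1% -> rare,
# 3 carriers ~ 0.12% -> common
panel = {f"p{i}" for i in range(2504)}
tre.carriers = frozenset({"case7", "p0", "p1"})
print("2 panel carriers of 2504: rare =", rarity_filter(tre, panel, 2504).is_rare)
tre.carriers = frozenset({"p0", "p1", "p2"})
print("3 panel carriers of 2504: rare =", rarity_filter(tre, panel, 2504).is_rare)
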