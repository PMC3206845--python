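"""In-silico bisulfite conversion of both strands of a CpG island region.

Builds a synthetic promoter-like region, numbers its CpG sites on the
sense strand, converts each strand for a hemimethylated molecule, and
shows which antisense sites the post-conversion poly-T run makes
unreadable by Sanger sequencing.
"""

from strandmeth import (ANTISENSE, SENSE, MethylationState, bisulfite_convert,
                        enumerate_cpg_sites, make_synthetic_region)

region = make_synthetic_region(site_count=30, seed=11)
site_map = enumerate_cpg_sites(region)
print(f"region: {len(region)} nt, {len(site_map)} CpG sites")
print("first sites (index, sense C position):",
      [(s.index, s.sense_c_pos) for s in list(site_map)[:5]])

# a hemimethylated molecule: antisense strand methylated, sense strand not
state = MethylationState({i: 1.0 for i in site_map.indices},
                         strand_mode="antisense_only")

for strand in (SENSE, ANTISENSE):
    t = bisulfite_convert(region, strand, state, site_map)
    retained = t.converted_sequence.count("C")
    print(f"{strand:9s}: {retained:2d} cytosines retained after conversion "
          f"(methylated CpG Cs on that strand only)")
    if t.unreadable_site_indices:
        lo = min(t.unreadable_site_indices)
        print(f"           poly-T run truncates the read: sites {lo}-"
              f"{max(t.unreadable_site_indices)} unreadable")

# Expected: the sense template keeps 0 Cs (unmethylated strand), the
# antisense template keeps its 30 methylated CpG Cs, and antisense sites
# past #20 are lost to the 16-bp poly-T run - which is why the analysis
# window is CpG sites 1-20.
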