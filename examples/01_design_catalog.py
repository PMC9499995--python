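"""Design the spike-in control panel.

Builds the factorial fragment grid (3 lengths x 3 G+C contents x 3 CpG
fractions, methylated + unmethylated), generates sequences that meet
each specification exactly, and computes equimolar pool amounts.
"""

from medipspike import (
    assign_amounts,
    build_catalog,
    generate_catalog_sequences,
    screen_secondary_structure,
)

catalog = build_catalog(include_failed=False, pool_mass_ng=0.01)
catalog = generate_catalog_sequences(catalog, seed=1)
catalog = assign_amounts(catalog, 0.01, "per-length-pool")

print(f"fragments in the final panel : {len(catalog)}")
f = catalog.fragments[0]
ok, stem = screen_secondary_structure(f.sequence)
print(f"example fragment             : {f.id}")
print(f"  length / G+C / CpGs        : {f.length_bp} bp / "
      f"{f.gc_content:.0%} / {f.cpg_count}")
print(f"  longest hairpin stem       : {stem} bp (pass={ok})")
print(f"  molecular mass             : {f.molecular_mass:,.0f} g/mol")
print(f"  known pool amount          : "
      f"{catalog.known_amounts[f.id]:.3g} pmol")
# The panel is the calibration ladder: every fragment's molar amount in
# the 0.01 ng pool is known, so sequencing counts can be converted to
# absolute picomoles.
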