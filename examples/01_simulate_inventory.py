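"""Generate a synthetic 25-site fallow-chronosequence inventory.

Builds the full study design (4 fallow categories + old-growth control,
5 replicate sites each, 4 transects of 50 m x 5 m per site), writes the
five census CSVs and prints record counts. Same seed -> same files.
"""
import tempfile
from pathlib import Path

from fallowcarbon import GeneratorConfig, generate_inventory, write_inventory

inv = generate_inventory(GeneratorConfig(seed=17))
out = Path(tempfile.mkdtemp(prefix="inventory_"))
write_inventory(inv, out)

print(f"wrote {out}/")
print(f"  sites:        {len(inv.sites):5d}  (5 per category)")
print(f"  live stems:   {len(inv.live_stems):5d}  (all >= 5 cm dbh)")
print(f"  ferns/abaca:  {len(inv.other_living):5d}")
print(f"  dead wood:    {len(inv.dead_wood):5d}")
print(f"  quadrats:     {len(inv.quadrats):5d}  (1 m^2, litter + undergrowth)")
# Counts scale with stand development: old-growth carries the most live
# stems, new fallows carry the felled/burnt dead wood.
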