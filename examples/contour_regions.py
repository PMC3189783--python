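"""Extract stdev*coeff contour maps and relate them to substituent sites.

After fitting the CoMSIA model, the product of each retained lattice
column's PLS coefficient and its standard deviation marks where field
variation drives predicted activity.  The 80th/20th percentiles of the
nonzero values define favoured/disfavoured level sets; connected regions
are reported with the nearest substituent position of the reference
compound (58), mirroring how contour maps are read against a template
structure.  Maps are exported as OpenDX and Gaussian cube files for
external 3D viewers.
"""

from pathlib import Path

from gridqsar import contours, io, pipeline
from gridqsar.config import RunConfig

cfg = RunConfig()
records, aligned, reference = pipeline.build_aligned_series(cfg)
result = pipeline.run_real_model(records, aligned, cfg, family="comsia")

out = Path("scratch/contours")
out.mkdir(parents=True, exist_ok=True)
for kind in ("comsia_S", "comsia_H", "comsia_D"):
    cmap = result.contour_maps[kind]
    regions, text = contours.substituent_report(cmap, reference)
    print(text)
    print()
    io.write_dx(cmap.values, cmap.grid, out / f"{kind}.dx")
    io.write_cube(cmap.values, cmap.grid, out / f"{kind}.cube", mol=reference)
print(f"volumetric maps written under {out}/ (favoured regions have positive peaks:")
print("field increase there raises predicted pKi; negative peaks are disfavoured)")
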