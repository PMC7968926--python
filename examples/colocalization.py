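"""Masked and puncta-referenced Pearson colocalization.

Simulates a field of thin (0.15 um) cytoneme-shaped objects whose two
fluorophore channels are correlated only at ligand puncta (rho = 0.8
there, 0 elsewhere). The membrane channel is segmented (Otsu +
skeleton length/width criteria), Pearson r is measured over the mask,
and again restricted to pixels in contact with segmented ligand
puncta.
"""

from cytoquant.coloc import (
    ChannelImage,
    mask_cytonemes,
    pearson_in_mask,
    puncta_referenced_pearson,
)
from cytoquant.simulate import gen_coloc_images

field = gen_coloc_images(rho=0.0, seed=3, puncta_density=0.5, rho_puncta=0.8)
membrane = ChannelImage(field.membrane, field.pixel_size, "membrane")
ch_a = ChannelImage(field.ch_a, field.pixel_size, "ch_a")
ch_b = ChannelImage(field.ch_b, field.pixel_size, "ch_b")
ref = ChannelImage(field.reference, field.pixel_size, "shh")

mask = mask_cytonemes(membrane)
print(f"cytoneme objects retained: {mask.n_objects}")
for obj in mask.objects:
    print(f"  length {obj.length_um:5.1f} um, width {obj.width_um:.2f} um")

whole = pearson_in_mask(ch_a, ch_b, mask)
puncta = puncta_referenced_pearson(ref, ch_a, ch_b, mask)
print(f"whole-mask Pearson r       : {whole.pearson_r:+.3f} "
      f"({whole.n_pixels} px)")
print(f"puncta-referenced Pearson r: {puncta.pearson_r:+.3f} "
      f"({puncta.n_pixels} px)")

# The whole-mask r sits near zero while the puncta-referenced r is
# high: the two proteins associate specifically at ligand puncta, not
# diffusely along the cytoneme.
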