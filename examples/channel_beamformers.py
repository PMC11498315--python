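"""Channel-domain beamformers on a simulated focused-linear-array point.

Builds a small per-beam channel-data cube for a single point scatterer at
the transmit focus and images it with DAS, coherence-factor weighting
(GCF), minimum variance (MV) and filtered delay-multiply-and-sum (F-DMAS),
printing the measured lateral width of each.
"""

import numpy as np

from gsnr import ArrayGeometry, psf_fwhm, simulate_channels
from gsnr.beamform import das_image, fdmas_image, gcf_image, mv_image

geom = ArrayGeometry(n_elements=48, n_beams=21, beam_spacing=0.1, fs=16e6,
                     depth_range=(28.0, 32.0))
cd = simulate_channels([(0.0, 30.0, 1.0)], geom)
z = np.arange(29.0, 31.0, 0.02)
print(f"{geom.n_elements} elements, pitch {geom.pitch} mm, f_c {geom.fc/1e6:.0f} MHz, "
      f"focus {geom.focus} mm")
print(f"diffraction estimate lambda*z/D = "
      f"{geom.wavelength*30.0/geom.aperture:.3f} mm\n")

for maker in (das_image, gcf_image, mv_image, fdmas_image):
    img = maker(cd, z)
    try:
        lat, ax = psf_fwhm(img)
        print(f"{img.label:7s} lateral FWHM {lat:.3f} mm, axial {ax:.3f} mm")
    except ValueError as exc:
        print(f"{img.label:7s} width not measurable here ({exc})")
print("\nAdaptive methods sharpen the point response; whether that narrows")
print("the *speckle* correlation cell is exactly what the robust resolution")
print("estimators in this package are for.")
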