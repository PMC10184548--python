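"""Olfactory ratio and its body-size context.

The ratio of the longest olfactory-bulb diameter to the longest
cerebral-hemisphere diameter (as a percentage) proxies olfactory acuity;
because it scales with body size, cross-taxon comparison uses
log10(ratio) against log10(body mass).
"""

from paleoneuro import (
    body_mass_bipedal,
    log_olfactory_point,
    olfactory_ratio,
)

bulb, cerebrum = 26.4, 52.2  # Ceratosuchops, mm
ratio = olfactory_ratio(bulb, cerebrum)
print(f"olfactory ratio: {ratio:.1f}%")

# Ceratosuchops has no usable femur; its body mass is borrowed from the
# similarly proportioned Baryonyx.
mass = body_mass_bipedal(350.0)
log_ratio, log_mass = log_olfactory_point(ratio, mass.mass_g)
print(
    f"log-log plot position: log10(ratio) = {log_ratio:.3f} "
    f"at log10(mass g) = {log_mass:.3f}"
)
# ~50.6% sits amid other large non-maniraptoran theropods (roughly 45-58%),
# i.e. unexceptional olfaction for a theropod of this size.
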