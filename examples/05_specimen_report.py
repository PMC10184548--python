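"""One-call specimen report: every derivable quantity, or why not.

A report computes whatever the available measurements allow -- body mass,
REQ per fill fraction, hearing estimates, olfactory and midbrain ratios --
and explicitly marks sections whose inputs are missing instead of silently
omitting them.
"""

from paleoneuro import SpecimenMeasurements, report_to_markdown, specimen_report

baryonyx = SpecimenMeasurements(
    taxon="Baryonyx",
    specimen_id="NHMUK PV R9951",
    endocast_volume_cm3=150.487,
    femoral_circumference_mm=350.0,
    ecd_mm=19.6,
    bcl_mm=104.5,
    midbrain_length_mm=61.6,
    medulla_length_mm=46.9,
    # no olfactory-bulb measurements: the bulbs are not preserved
)

print(report_to_markdown(specimen_report(baryonyx)))
# The olfaction section reads "not computable" because the olfactory bulbs
# are not preserved in this specimen; everything else re-derives the
# comparative-table values for this taxon.
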