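"""Run all fifteen preset measures on the hypothetical patient.

With a single patient, every percentile equals that patient's count, so
the table below is exactly the worked-example column: the count is 3
under the default and rises to 4 when combination products are
dissected into ingredients (v5, v6), when the allowable index gap is a
fixed 90 or 180 days (v8, v9), or when as-needed drugs get a wider gap
(v13); it falls to 2 when scope is restricted to oral products (v2).
"""

from drugtally import PRESET_NAMES, comparison_report, preset, render_report_text
from drugtally.synthetic import table3_fixture

history, dictionary = table3_fixture()
measures = [preset(name) for name in PRESET_NAMES]
report = comparison_report([history], measures, dictionary)
print(render_report_text(report[["measure_id", "description", "p50"]]))
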