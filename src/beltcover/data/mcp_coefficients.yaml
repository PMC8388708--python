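# Published quartic coefficients for the manure-coverage-proportion (MCP)
# growth curves fitted to 21-week mean field data.  Units: percent per hour^n.
# mcp48: belt cleared every 48 h, valid for h in [1, 48].
# mcp24: belt cleared every 24 h, valid for h in [1, 24].
mcp48:
  coefficients: [-3.359e-5, 3.621e-3, -0.1648, 5.081, -4.105]
  domain_hours: [1, 48]
mcp24:
  coefficients: [3.234e-4, -1.861e-2, 0.2786, 1.992, 1.147]
  domain_hours: [1, 24]
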