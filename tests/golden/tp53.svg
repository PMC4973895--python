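<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="740.00" height="128.00" viewBox="0 0 740.00 128.00"><rect class="backbone" x="15.00" y="90.00" width="710.00" height="14.00" fill="#BABDB6" /><rect class="motif motif-low_complexity" x="128.82" y="90.00" width="52.39" height="14.00" fill="#00C0C0" /><g class="domain"><rect x="24.03" y="86.00" width="43.36" height="22.00" rx="3.00" fill="#5B8AC6"><title>P53_TAD: P53 transactivation motif</title></rect><text x="45.71" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">..TAD</text></g><g class="domain"><rect x="184.82" y="86.00" width="350.48" height="22.00" rx="3.00" fill="#C0354F"><title>P53: P53 DNA-binding domain</title></rect><text x="360.06" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">P53 DNA-binding domain</text></g><g class="domain"><rect x="587.70" y="86.00" width="74.07" height="22.00" rx="3.00" fill="#3B8C6E"><title>P53_tetramer: P53 tetramerisation motif</title></rect><text x="624.73" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">..tetramer</text></g><line class="tick" x1="24.94" y1="104.00" x2="24.94" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="24.94" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">6</text><line class="tick" x1="66.49" y1="104.00" x2="66.49" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="66.49" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">29</text><line class="tick" x1="185.73" y1="104.00" x2="185.73" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="185.73" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">95</text><line class="tick" x1="330.25" y1="104.00" x2="330.25" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="330.25" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">175</text><line class="tick" x1="456.72" y1="104.00" x2="456.72" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="456.72" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">245</text><line class="tick" x1="507.30" y1="104.00" x2="507.30" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="507.30" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">273</text><line class="tick" x1="534.40" y1="104.00" x2="534.40" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="534.40" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">288</text><line class="tick" x1="588.60" y1="104.00" x2="588.60" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="588.60" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">318</text><line class="tick" x1="660.87" y1="104.00" x2="660.87" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="660.87" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">358</text><line class="tick" x1="724.10" y1="104.00" x2="724.10" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="724.10" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">393</text><line class="stem" x1="330.25" y1="90.00" x2="330.25" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="456.72" y1="90.00" x2="456.72" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="462.14" y1="90.00" x2="462.14" y2="54.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="507.30" y1="90.00" x2="507.30" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="523.56" y1="90.00" x2="523.56" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><circle class="head" cx="330.25" cy="66.00" r="4.00" fill="#D40000"><title>R175H</title></circle><circle class="head" cx="456.72" cy="66.00" r="4.00" fill="#D40000"><title>G245S</title></circle><circle class="head" cx="462.14" cy="54.00" r="4.00" fill="#D40000"><title>R248Q</title></circle><circle class="head" cx="507.30" cy="66.00" r="4.00" fill="#FF8800"><title>R273H</title></circle><circle class="head" cx="523.56" cy="66.00" r="12.00" fill="#D40000"><title>R282W</title></circle></svg>
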