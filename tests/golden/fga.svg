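<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="740.00" height="128.00" viewBox="0 0 740.00 128.00"><rect class="backbone" x="15.00" y="90.00" width="710.00" height="14.00" fill="#BABDB6" /><rect class="motif motif-sig_p" x="15.00" y="90.00" width="15.58" height="14.00" fill="#F0A000" /><rect class="motif motif-disorder" x="198.65" y="90.00" width="136.10" height="14.00" fill="#555555" /><rect class="motif motif-low_complexity" x="440.51" y="90.00" width="41.81" height="14.00" fill="#00C0C0" /><g class="domain"><rect x="36.32" y="86.00" width="137.74" height="22.00" rx="3.00" fill="#2E86AB"><title>Fib_alpha: Fibrinogen alpha/beta chain family</title></rect><text x="105.18" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">Fib_alpha</text></g><g class="domain"><rect x="358.52" y="86.00" width="58.21" height="22.00" rx="3.00" fill="#A23B72"><title>Fib_coil: Fibrinogen alpha chain coiled-coil region</title></rect><text x="387.63" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">Fib_coil</text></g><g class="domain"><rect x="517.58" y="86.00" width="196.77" height="22.00" rx="3.00" fill="#F18F01"><title>Fib_aC: Fibrinogen alpha C domain</title></rect><text x="615.96" y="101.20" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#FFFFFF">Fibrinogen alpha C domain</text></g><line class="tick" x1="15.41" y1="104.00" x2="15.41" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="15.41" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">1</text><line class="tick" x1="36.73" y1="104.00" x2="36.73" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="36.73" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">27</text><line class="tick" x1="99.04" y1="104.00" x2="99.04" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="99.04" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">103</text><line class="tick" x1="173.64" y1="104.00" x2="173.64" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="173.64" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">194</text><line class="tick" x1="272.03" y1="104.00" x2="272.03" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="272.03" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">314</text><line class="tick" x1="358.93" y1="104.00" x2="358.93" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="358.93" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">420</text><line class="tick" x1="416.32" y1="104.00" x2="416.32" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="416.32" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">490</text><line class="tick" x1="459.77" y1="104.00" x2="459.77" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="459.77" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">543</text><line class="tick" x1="517.98" y1="104.00" x2="517.98" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="517.98" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">614</text><line class="tick" x1="588.49" y1="104.00" x2="588.49" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="588.49" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">700</text><line class="tick" x1="622.11" y1="104.00" x2="622.11" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="622.11" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">741</text><line class="tick" x1="713.93" y1="104.00" x2="713.93" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="713.93" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">853</text><line class="stem" x1="99.04" y1="90.00" x2="99.04" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="272.03" y1="90.00" x2="272.03" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="459.77" y1="90.00" x2="459.77" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="588.49" y1="90.00" x2="588.49" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><line class="stem" x1="622.11" y1="90.00" x2="622.11" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><circle class="head" cx="99.04" cy="66.00" r="5.00" fill="#D40000"><title>G103R</title></circle><text class="variant-label" x="99.04" y="58.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="10.80" fill="#333333">G103R</text><circle class="head" cx="272.03" cy="66.00" r="5.00" fill="#D40000"><title>S314F</title></circle><text class="variant-label" x="272.03" y="58.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="10.80" fill="#333333">S314F</text><circle class="head" cx="459.77" cy="66.00" r="5.00" fill="#D40000"><title>P543L</title></circle><text class="variant-label" x="459.77" y="58.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="10.80" fill="#333333">P543L</text><circle class="head" cx="588.49" cy="66.00" r="5.00" fill="#D40000"><title>R700C</title></circle><text class="variant-label" x="588.49" y="58.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="10.80" fill="#333333">R700C</text><circle class="head" cx="622.11" cy="66.00" r="5.00" fill="#D40000"><title>W741*</title></circle><text class="variant-label" x="622.11" y="58.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="10.80" fill="#333333">W741*</text></svg>
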