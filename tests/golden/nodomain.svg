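<?xml version="1.0" encoding="UTF-8"?>
<svg xmlns="http://www.w3.org/2000/svg" width="740.00" height="128.00" viewBox="0 0 740.00 128.00"><rect class="backbone" x="15.00" y="90.00" width="710.00" height="14.00" fill="#BABDB6" /><line class="tick" x1="17.96" y1="104.00" x2="17.96" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="17.96" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">1</text><line class="tick" x1="278.29" y1="104.00" x2="278.29" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="278.29" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">45</text><line class="tick" x1="722.04" y1="104.00" x2="722.04" y2="108.00" stroke="#333333" stroke-width="1.00" /><text class="tick-label" x="722.04" y="120.00" text-anchor="middle" font-family="'DejaVu Sans',sans-serif" font-size="12.00" fill="#333333">120</text><line class="stem" x1="278.29" y1="90.00" x2="278.29" y2="66.00" stroke="#BABDB6" stroke-width="2.00" /><circle class="head" cx="278.29" cy="66.00" r="5.00" fill="#D40000"><title>E45K</title></circle></svg>
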