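<svg xmlns="http://www.w3.org/2000/svg" width="800" height="600" viewBox="0 0 800 600">
  <!-- Standard eukaryotic-cell view. Regions: class="compartment-region",
       id = compartment name with spaces replaced by underscores.
       Draw order is outer-first so nested fills stay visible. -->
  <rect id="Extracellular_region" class="compartment-region" x="0" y="0" width="800" height="600" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Plasma_membrane" class="compartment-region" cx="400" cy="300" rx="360" ry="270" fill="#ffffff" stroke="#555555" stroke-width="2"/>
  <ellipse id="Cytoplasm" class="compartment-region" cx="400" cy="300" rx="332" ry="243" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Nucleus" class="compartment-region" cx="400" cy="270" rx="110" ry="92" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Mitochondrion" class="compartment-region" cx="185" cy="200" rx="55" ry="28" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Endoplasmic_reticulum" class="compartment-region" cx="560" cy="195" rx="80" ry="40" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Golgi_apparatus" class="compartment-region" cx="585" cy="390" rx="72" ry="32" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Endosome" class="compartment-region" cx="250" cy="405" rx="42" ry="30" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Lysosome" class="compartment-region" cx="352" cy="472" r="26" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Peroxisome" class="compartment-region" cx="152" cy="300" r="22" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Vacuole" class="compartment-region" cx="472" cy="472" rx="46" ry="30" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Ribosome" class="compartment-region" cx="268" cy="132" r="14" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <rect id="Cytoskeleton" class="compartment-region" x="118" y="360" width="100" height="14" rx="7" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Intracellular_vesicle" class="compartment-region" cx="548" cy="295" r="18" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>

  <text class="compartment-label" x="12" y="20" font-size="12" fill="#222222">Extracellular region</text>
  <text class="compartment-label" x="400" y="48" font-size="12" fill="#222222" text-anchor="middle">Plasma membrane</text>
  <text class="compartment-label" x="400" y="540" font-size="12" fill="#222222" text-anchor="middle">Cytoplasm</text>
  <text class="compartment-label" x="400" y="274" font-size="12" fill="#222222" text-anchor="middle">Nucleus</text>
  <text class="compartment-label" x="185" y="164" font-size="12" fill="#222222" text-anchor="middle">Mitochondrion</text>
  <text class="compartment-label" x="560" y="147" font-size="12" fill="#222222" text-anchor="middle">Endoplasmic reticulum</text>
  <text class="compartment-label" x="585" y="442" font-size="12" fill="#222222" text-anchor="middle">Golgi apparatus</text>
  <text class="compartment-label" x="250" y="452" font-size="12" fill="#222222" text-anchor="middle">Endosome</text>
  <text class="compartment-label" x="352" y="516" font-size="12" fill="#222222" text-anchor="middle">Lysosome</text>
  <text class="compartment-label" x="152" y="338" font-size="12" fill="#222222" text-anchor="middle">Peroxisome</text>
  <text class="compartment-label" x="472" y="518" font-size="12" fill="#222222" text-anchor="middle">Vacuole</text>
  <text class="compartment-label" x="268" y="110" font-size="12" fill="#222222" text-anchor="middle">Ribosome</text>
  <text class="compartment-label" x="168" y="392" font-size="12" fill="#222222" text-anchor="middle">Cytoskeleton</text>
  <text class="compartment-label" x="548" y="330" font-size="12" fill="#222222" text-anchor="middle">Intracellular vesicle</text>
</svg>
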