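<svg xmlns="http://www.w3.org/2000/svg" width="800" height="600" viewBox="0 0 800 600">
  <!-- Endosomal-trafficking view: plasma membrane, early/late/recycling
       endosomes, lysosome, Golgi, vesicles. Same region conventions as the
       standard view. The inner backdrop is decorative (no region class). -->
  <ellipse id="Plasma_membrane" class="compartment-region" cx="400" cy="300" rx="370" ry="280" fill="#ffffff" stroke="#555555" stroke-width="2"/>
  <ellipse id="backdrop" cx="400" cy="300" rx="342" ry="252" fill="#fafafa" stroke="#555555" stroke-width="1"/>
  <ellipse id="Early_endosome" class="compartment-region" cx="225" cy="245" rx="62" ry="42" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Recycling_endosome" class="compartment-region" cx="400" cy="165" rx="56" ry="36" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Late_endosome" class="compartment-region" cx="545" cy="275" rx="56" ry="42" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Lysosome" class="compartment-region" cx="545" cy="415" r="36" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <ellipse id="Golgi_apparatus" class="compartment-region" cx="360" cy="478" rx="108" ry="34" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>
  <circle id="Intracellular_vesicle" class="compartment-region" cx="300" cy="370" r="24" fill="#ffffff" stroke="#555555" stroke-width="1.5"/>

  <text class="compartment-label" x="400" y="40" font-size="12" fill="#222222" text-anchor="middle">Plasma membrane</text>
  <text class="compartment-label" x="225" y="192" font-size="12" fill="#222222" text-anchor="middle">Early endosome</text>
  <text class="compartment-label" x="400" y="118" font-size="12" fill="#222222" text-anchor="middle">Recycling endosome</text>
  <text class="compartment-label" x="545" y="222" font-size="12" fill="#222222" text-anchor="middle">Late endosome</text>
  <text class="compartment-label" x="618" y="420" font-size="12" fill="#222222">Lysosome</text>
  <text class="compartment-label" x="360" y="532" font-size="12" fill="#222222" text-anchor="middle">Golgi apparatus</text>
  <text class="compartment-label" x="300" y="412" font-size="12" fill="#222222" text-anchor="middle">Intracellular vesicle</text>
</svg>
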