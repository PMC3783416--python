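// Standard keyboard controls and billboard handling for 3-d PDF figures.
// Attached to the 3-d annotation and run by the viewer's 3-d JavaScript
// engine on figure activation.  Key bindings (views 1-7 are view dictionaries
// embedded in the PDF and are selected by index):
//
//   1..7   select preset view (front, back, left, right, top, bottom, oblique)
//   +, -   zoom in, out
//   [, ]   roll camera clockwise, counter-clockwise
//   arrows swing camera left/right/up/down
//   <, >   decrease, increase camera movement delta
//   Shift-A  toggle autospin
//   /, *   decrease, increase autospin speed
//
// Billboard leaves of the model tree (node names beginning with "BB") are
// collected at initialisation and reoriented to face the camera before every
// redraw.

var cameraDelta = 0.1;
var autospin = false;
var autospinSpeed = 1.0;
var billboards = [];

function collectBillboards() {
  billboards = [];
  for (var i = 0; i < scene.nodes.count; i++) {
    var node = scene.nodes.getByIndex(i);
    if (node.name.indexOf("BB") === 0) billboards.push(node);
  }
}

function faceCamera(node) {
  var cam = scene.cameras.getByIndex(0);
  var c = node.computeBoundingBox().center;
  var dir = cam.position.subtract(c);
  dir.normalize();
  // minimal rotation taking the quad normal onto dir, about the quad centre
  node.transform.setView(dir, cam.up);
  node.transform.translateInPlace(c);
}

runtime.addEventHandler(new RenderEventHandler());
function onEvent(event) {
  for (var i = 0; i < billboards.length; i++) faceCamera(billboards[i]);
  event.canvas.update();
}

runtime.addEventHandler(new KeyEventHandler());
function onKeyEvent(event) {
  var ch = String.fromCharCode(event.characterCode);
  var cam = scene.cameras.getByIndex(0);
  if (ch >= "1" && ch <= "7") {
    runtime.setView(parseInt(ch, 10) - 1);
  } else if (ch === "+") { cam.roo *= 1.0 - cameraDelta; }
  else if (ch === "-") { cam.roo *= 1.0 + cameraDelta; }
  else if (ch === "[") { cam.roll(-5); }
  else if (ch === "]") { cam.roll(5); }
  else if (ch === "<") { cameraDelta /= 1.5; }
  else if (ch === ">") { cameraDelta *= 1.5; }
  else if (ch === "A") { autospin = !autospin; }
  else if (ch === "/") { autospinSpeed /= 1.5; }
  else if (ch === "*") { autospinSpeed *= 1.5; }
}

collectBillboards();
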